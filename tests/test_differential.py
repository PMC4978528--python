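"""Differential calling, the moderated test and knockdown responses."""

import math
import subprocess
import textwrap
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import stemsplice as ss
from stemsplice.differential import (
    _criteria,
    call_alternative,
    direction_association,
    fit_moderated_test,
    kd_response,
    summarize_group,
)


def make_table(x1_values, diff_values, n_events=1, noise_seed=None):
    """InclusionTable with one row of given X1/diff values (all covered)."""
    cols = [f"X1_{i}" for i in range(len(x1_values))] + [
        f"D_{i}" for i in range(len(diff_values))
    ]
    data = np.array([list(x1_values) + list(diff_values)] * n_events, dtype=float)
    if noise_seed is not None:
        rng = np.random.default_rng(noise_seed)
        data = np.clip(data + rng.normal(0, 3, size=data.shape), 0, 100)
    values = pd.DataFrame(
        data, index=pd.Index([f"e{i}" for i in range(n_events)], name="event_id"),
        columns=cols,
    )
    covered = pd.DataFrame(True, index=values.index, columns=cols)
    manifest = ss.SampleManifest(
        [ss.SampleInfo(c, "X1", i) for i, c in enumerate(cols) if c.startswith("X1")]
        + [ss.SampleInfo(c, "XINS", i) for i, c in enumerate(cols) if c.startswith("D")]
    )
    return ss.InclusionTable(values, covered), manifest


class TestCallAlternative:
    def test_all_intermediate(self):
        assert call_alternative([50.0] * 10)

    def test_all_constitutive(self):
        assert not call_alternative([100.0] * 10)

    def test_one_in_band_of_ten(self):
        assert call_alternative([100.0] * 9 + [70.0])

    def test_range_rule_alone(self):
        # nothing in the 10-90 band but range >= 25
        assert call_alternative([5.0, 95.0])


class TestSummarizeGroup:
    def test_basic_statistics(self):
        s = summarize_group([20, 22, 25, 30])
        assert s.mean == pytest.approx(24.25)
        assert s.range == pytest.approx(10)
        assert (s.min, s.max) == (20, 30)

    def test_mean80_drops_most_distant(self):
        s = summarize_group([10, 10, 10, 90, 90], reference_mean=10)
        assert s.mean80 == pytest.approx(30.0)  # one 90 dropped, mean of rest

    def test_mean80_tie_drops_later_sample(self):
        # distances: [0, 80, 80]; k=1; the later 90 is dropped
        s = summarize_group([10, 90, 90], reference_mean=10)
        assert s.mean80 == pytest.approx(50.0)

    def test_single_value(self):
        s = summarize_group([42.0])
        assert (s.mean, s.min, s.max, s.sd, s.range) == (42.0, 42.0, 42.0, 0.0, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_group([])


class TestModeratedTest:
    def test_equal_means_give_null(self):
        table, manifest = make_table([50, 52, 48], [50, 52, 48, 50])
        res = fit_moderated_test(table, manifest.samples_in("X1"), manifest.diff_samples())
        row = res.table.iloc[0]
        assert row["t_mod"] == pytest.approx(0.0, abs=1e-12)
        assert row["p_value"] == pytest.approx(1.0)

    def test_zero_prior_df_recovers_ordinary_t(self):
        rng = np.random.default_rng(5)
        table, manifest = make_table([60] * 5, [40] * 6, n_events=50, noise_seed=5)
        a, b = manifest.samples_in("X1"), manifest.diff_samples()
        res = fit_moderated_test(table, a, b, prior_df=0.0, prior_var=1.0)
        for eid in res.events:
            va = table.values.loc[eid, a].to_numpy()
            vb = table.values.loc[eid, b].to_numpy()
            t_ref, p_ref = stats.ttest_ind(va, vb, equal_var=True)
            assert res.table.loc[eid, "t_mod"] == pytest.approx(t_ref, abs=1e-9)
            assert res.table.loc[eid, "p_value"] == pytest.approx(p_ref, abs=1e-9)

    def test_infinite_prior_df_collapses_to_prior_variance(self):
        table, manifest = make_table([60] * 5, [40] * 6, n_events=30, noise_seed=6)
        res = fit_moderated_test(
            table, manifest.samples_in("X1"), manifest.diff_samples(),
            prior_df=math.inf, prior_var=25.0,
        )
        assert np.allclose(res.table["s2_post"], 25.0)

    def test_p_monotone_in_mean_difference(self):
        deltas = [5, 10, 20, 30]
        ps = []
        for d in deltas:
            table, manifest = make_table([50 + d, 52 + d, 48 + d], [50, 52, 48, 50])
            res = fit_moderated_test(
                table, manifest.samples_in("X1"), manifest.diff_samples(),
                prior_df=4.0, prior_var=4.0,
            )
            ps.append(float(res.table["p_value"].iloc[0]))
        assert ps == sorted(ps, reverse=True)

    def test_matches_limma_oracle(self, tmp_path):
        """Independent cross-check of t, p, prior fit and B against R limma."""
        rng = np.random.default_rng(17)
        n_events, na, nb = 60, 4, 5
        data = rng.normal(50, 6, size=(n_events, na + nb))
        data[:10, :na] += 25  # some truly shifted events
        cols = [f"A{i}" for i in range(na)] + [f"B{i}" for i in range(nb)]
        values = pd.DataFrame(
            np.clip(data, 0, 100),
            index=pd.Index([f"e{i}" for i in range(n_events)], name="event_id"),
            columns=cols,
        )
        covered = pd.DataFrame(True, index=values.index, columns=cols)
        table = ss.InclusionTable(values, covered)
        res = fit_moderated_test(table, cols[:na], cols[na:])

        mat = tmp_path / "m.tsv"
        values.to_csv(mat, sep="\t")
        out = tmp_path / "limma.tsv"
        script = tmp_path / "run.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(limma))
            X <- as.matrix(read.table("{mat}", header=TRUE, row.names=1, sep="\\t"))
            groups <- factor(c(rep("A", {na}), rep("B", {nb})), levels=c("A","B"))
            design <- model.matrix(~0+groups)
            colnames(design) <- c("A","B")
            fit <- lmFit(X, design)
            fit <- contrasts.fit(fit, makeContrasts(A-B, levels=design))
            fit <- eBayes(fit, proportion=0.01)
            out <- data.frame(t=fit$t[,1], p=fit$p.value[,1], b=fit$lods[,1],
                              d0=fit$df.prior, s0=fit$s2.prior)
            write.table(out, "{out}", sep="\\t", quote=FALSE)
        """))
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(out, sep="\t")
        ref.index = values.index
        assert res.d0 == pytest.approx(float(ref["d0"].iloc[0]), rel=1e-5)
        assert res.s0_sq == pytest.approx(float(ref["s0"].iloc[0]), rel=1e-5)
        assert np.allclose(res.table["t_mod"], ref["t"], atol=1e-6)
        assert np.allclose(res.table["p_value"], ref["p"], atol=1e-8)
        assert np.allclose(res.table["b_statistic"], ref["b"], atol=1e-4)


class TestCriteria:
    def test_q1_large_shift_with_tight_group(self):
        sx1 = summarize_group([90, 92, 95])
        sdiff = summarize_group([20, 22, 25, 30], reference_mean=sx1.mean)
        met = _criteria(sx1, sdiff)
        assert "Q1" in met

    def test_no_call_when_groups_identical(self):
        sx1 = summarize_group([50, 50, 50])
        sdiff = summarize_group([50, 50, 50, 50], reference_mean=50.0)
        assert _criteria(sx1, sdiff) == frozenset()

    def test_q3_qualitative_pattern(self):
        sx1 = summarize_group([99, 98, 100, 98])
        sdiff = summarize_group([85, 80, 70, 88], reference_mean=sx1.mean)
        assert "Q3" in _criteria(sx1, sdiff)

    def test_q3_needs_four_samples_per_group(self):
        sx1 = summarize_group([99, 98, 100])
        sdiff = summarize_group([85, 80, 70, 88], reference_mean=sx1.mean)
        assert "Q3" not in _criteria(sx1, sdiff)

    @given(seed=st.integers(0, 500))
    @settings(max_examples=60, deadline=None)
    def test_permutation_invariance_and_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        x1 = rng.uniform(0, 100, size=5)
        diff = rng.uniform(0, 100, size=6)
        sx1 = summarize_group(x1)
        sdiff = summarize_group(diff, reference_mean=sx1.mean)
        met = _criteria(sx1, sdiff)
        # permuting samples within groups leaves the criteria unchanged
        # (mean80 can change at distance ties; unequal values avoid that)
        px1 = summarize_group(rng.permutation(x1))
        pdiff = summarize_group(rng.permutation(diff), reference_mean=px1.mean)
        assert _criteria(px1, pdiff) == met
        # swapping the group labels preserves Q1/Q3 (Q2 is mean80-asymmetric)
        sdiff_as_x1 = summarize_group(diff)
        sx1_as_diff = summarize_group(x1, reference_mean=sdiff_as_x1.mean)
        swapped = _criteria(sdiff_as_x1, sx1_as_diff)
        assert ("Q1" in met) == ("Q1" in swapped)
        assert ("Q3" in met) == ("Q3" in swapped)


class TestCallerEndToEnd:
    def test_direction_flips_when_groups_swap(self, small_dataset):
        cfg, events, truth, manifest, counts, table = small_dataset
        calls, _ = ss.call_neoblast_differential(table, manifest)
        assert calls, "expected at least one differential call"
        swapped_manifest = ss.SampleManifest(
            [
                ss.SampleInfo(
                    s.sample_id,
                    {"X1": "XINS", "XINS": "X1", "WW_DEPLETED": "X1"}.get(s.group, s.group),
                    s.replicate,
                )
                for s in manifest
            ]
        )
        # with 6 X1 <-> 8 diff swapped the pool sizes change, so compare the
        # direction of events called both ways
        swapped_calls, _ = ss.call_neoblast_differential(table, swapped_manifest)
        by_id = {c.event_id: c for c in swapped_calls}
        flipped = [
            (c.direction, by_id[c.event_id].direction)
            for c in calls
            if c.event_id in by_id
        ]
        assert flipped
        assert all(a != b for a, b in flipped)

    def test_background_is_non_differential_and_alternative(self, small_dataset):
        cfg, events, truth, manifest, counts, table = small_dataset
        background = ss.define_background(table, manifest)
        assert background
        called = {c.event_id for c in ss.call_neoblast_differential(table, manifest)[0]}
        assert not background & called
        assert not truth.loc[sorted(background)]["differential"].any()


class TestKdResponse:
    def _call(self, delta):
        return ss.DifferentialCall(
            event_id="e0",
            criteria_met=frozenset({"Q1"}),
            p_value=0.01,
            direction="X1_INCLUDED" if delta > 0 else "X1_EXCLUDED",
            delta_psi=delta,
        )

    def _tables(self, treated, control):
        def one(name, v):
            values = pd.DataFrame({name: [v]}, index=pd.Index(["e0"], name="event_id"))
            covered = pd.DataFrame({name: [True]}, index=values.index)
            return ss.InclusionTable(values, covered)

        return one("kd", treated), one("ctl", control)

    @pytest.mark.parametrize(
        "treated, control, x1_delta, responsive",
        [
            (40.0, 20.0, 30.0, True),  # +20 toward the X1 pattern
            (10.0, 20.0, 30.0, False),  # wrong direction
            (34.9, 20.0, 30.0, False),  # |delta| = 14.9 below threshold
            (5.0, 20.0, -30.0, True),  # X1-excluded event moving down
        ],
    )
    def test_response_rule(self, treated, control, x1_delta, responsive):
        t, c = self._tables(treated, control)
        fraction, per_event = kd_response(t, c, [self._call(x1_delta)])
        assert bool(per_event["responsive"].iloc[0]) is responsive
        assert fraction == (1.0 if responsive else 0.0)

    def test_empty_eligible_set_is_an_error(self):
        t, c = self._tables(40.0, 20.0)
        c.covered.iloc[0, 0] = False
        with pytest.raises(ValueError, match="covered"):
            kd_response(t, c, [self._call(30.0)])


class TestDirectionAssociation:
    def test_nine_of_ten_opposite(self):
        a = {f"e{i}": 20.0 for i in range(10)}
        b = {f"e{i}": -20.0 for i in range(9)}
        b["e9"] = 20.0
        p, k, n = direction_association(a, b, "opposite")
        assert (k, n) == (9, 10)
        assert p == pytest.approx(11 / 1024)

    def test_five_of_ten(self):
        a = {f"e{i}": 20.0 for i in range(10)}
        b = {f"e{i}": (-20.0 if i < 5 else 20.0) for i in range(10)}
        p, k, n = direction_association(a, b, "opposite")
        expected = sum(math.comb(10, i) for i in range(5, 11)) / 1024
        assert p == pytest.approx(expected)
        assert p == pytest.approx(0.623, abs=5e-4)

    def test_all_of_n_closed_form(self):
        for n in (1, 4, 12):
            a = {f"e{i}": 16.0 for i in range(n)}
            b = {f"e{i}": -16.0 for i in range(n)}
            p, k, m = direction_association(a, b, "opposite")
            assert (k, m) == (n, n)
            assert p == pytest.approx(0.5**n)

    def test_threshold_excludes_small_shifts(self):
        a = {"e0": 20.0, "e1": 14.9}
        b = {"e0": -20.0, "e1": -20.0}
        p, k, n = direction_association(a, b, "opposite")
        assert n == 1

    def test_exact_fraction_against_enumeration(self):
        a = {f"e{i}": 18.0 for i in range(7)}
        b = {f"e{i}": (-18.0 if i < 6 else 18.0) for i in range(7)}
        p, k, n = direction_association(a, b, "opposite")
        exact = sum(Fraction(math.comb(7, i), 2**7) for i in range(6, 8))
        assert p == pytest.approx(float(exact), abs=1e-15)
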