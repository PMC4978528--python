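"""Differential inclusion calling between stem-cell and differentiated samples.

An event is "alternatively spliced" when its inclusion level sits in the
10-90 band in at least 10% of covered samples, or spans a range of at least
25 across them.  Stem-cell (X1) versus differentiated ("diff": Xins plus
neoblast-depleted whole worms) differential events must pass a moderated
empirical-Bayes test (p < alpha) and at least one of three non-mutually
exclusive criteria capturing quantitative shifts (Q1), robust shifts against
a trimmed differentiated mean (Q2), and qualitative presence/absence
patterns (Q3).

The moderated test shrinks per-event pooled variances toward a prior
estimated across events by moment-matching the scaled-F distribution of the
sample variances, then refers the shrunken t statistic to a t distribution
with augmented degrees of freedom; the log posterior odds of differential
inclusion (B statistic) is reported alongside but never gated on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .core import InclusionTable, SampleManifest

__all__ = [
    "GroupSummary",
    "ModeratedTestResult",
    "DifferentialCall",
    "call_alternative",
    "summarize_group",
    "fit_moderated_test",
    "call_neoblast_differential",
    "define_background",
    "kd_response",
    "direction_association",
]


@dataclass(frozen=True)
class GroupSummary:
    """Per-event inclusion statistics within one sample group."""

    n_covered: int
    mean: float
    sd: float
    min: float
    max: float
    mean80: float | None = None

    @property
    def range(self) -> float:
        return self.max - self.min


def call_alternative(values: Sequence[float]) -> bool:
    """Whether covered inclusion levels mark the event as alternatively spliced.

    True iff at least 10% of covered samples have a value in [10, 90], or the
    value range across covered samples is at least 25.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        return False
    in_band = np.mean((v >= 10) & (v <= 90))
    return in_band >= 0.10 or (v.max() - v.min()) >= 25


def summarize_group(
    values: Sequence[float], reference_mean: float | None = None
) -> GroupSummary:
    """Summary statistics for one group, in manifest order.

    When ``reference_mean`` is given (the X1 mean, for the differentiated
    group) the trimmed ``mean80`` is also computed: the ceil(0.2 * n) values
    most distant from the reference are dropped (distance ties broken by
    dropping the later sample) and the rest averaged.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("summarize_group requires at least one value")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    mean80 = None
    if reference_mean is not None:
        k = math.ceil(0.2 * v.size)
        dist = np.abs(v - reference_mean)
        # stable sort: among equal distances the earlier sample is kept
        order = np.lexsort((np.arange(v.size), dist))
        kept = order[: v.size - k] if k < v.size else order[:0]
        mean80 = float(np.mean(v[kept])) if kept.size else float("nan")
    return GroupSummary(
        n_covered=int(v.size),
        mean=float(np.mean(v)),
        sd=sd,
        min=float(v.min()),
        max=float(v.max()),
        mean80=mean80,
    )


# -- empirical-Bayes moderated test ------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration)."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) / y < 1e-8:
            break
    return y


def _fit_f_dist(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match a scaled-F prior (d0, s0^2) to sample variances.

    Works on log variances: e_g = log s2_g - digamma(d_g/2) + log(d_g/2) has
    mean log s0^2 + digamma(d0/2) - log(d0/2) and variance trigamma(d_g/2) +
    trigamma(d0/2) under the hierarchical model.
    """
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    s2, df = s2[ok], df[ok]
    if s2.size == 0:
        raise ValueError("no positive finite variances to fit the prior")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    if s2.size > 1:
        evar = float(np.sum((e - emean) ** 2) / (s2.size - 1))
    else:
        evar = 0.0
    evar -= float(np.mean(special.polygamma(1, df / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(emean)
    return d0, s0_sq


def _tmixture_vector(
    tstat: np.ndarray,
    stdev_unscaled: np.ndarray,
    df: np.ndarray,
    proportion: float,
    v0_lim: tuple[float, float] = (0.01, 16.0),
) -> float:
    """Estimate the prior variance of the (unscaled) effect for the B statistic
    from the top fraction of moderated t statistics."""
    ngenes = tstat.size
    ntarget = math.ceil(proportion / 2.0 * ngenes)
    if ntarget < 1:
        return float("nan")
    p = max(ntarget / ngenes, proportion)
    tstat = np.abs(tstat.astype(float))
    df = np.where(np.isfinite(df), df, 1e6)
    max_df = float(np.max(df))
    smaller = df < max_df
    if smaller.any():
        tail_log = stats.t.logsf(tstat[smaller], df[smaller])
        tstat = tstat.copy()
        tstat[smaller] = stats.t.isf(np.exp(tail_log), max_df)
    order = np.argsort(-tstat)[:ntarget]
    tt = tstat[order]
    v1 = stdev_unscaled[order] ** 2
    r = np.arange(1, ntarget + 1)
    p0 = 2.0 * stats.t.sf(tt, max_df)
    ptarget = ((r - 0.5) / ngenes - (1.0 - p) * p0) / p
    v0 = np.zeros(ntarget)
    pos = ptarget > p0
    if pos.any():
        qtarget = stats.t.isf(ptarget[pos] / 2.0, max_df)
        v0[pos] = v1[pos] * ((tt[pos] / qtarget) ** 2 - 1.0)
    v0 = np.clip(v0, v0_lim[0], v0_lim[1])
    return float(np.mean(v0))


@dataclass
class ModeratedTestResult:
    """Per-event moderated statistics plus the shared prior (d0, s0^2)."""

    table: pd.DataFrame = field(repr=False)
    d0: float = float("nan")
    s0_sq: float = float("nan")

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]

    @property
    def events(self) -> pd.Index:
        return self.table.index


def fit_moderated_test(
    table: InclusionTable,
    group_a: Sequence[str],
    group_b: Sequence[str],
    *,
    prior_df: float | None = None,
    prior_var: float | None = None,
    prior_proportion: float = 0.01,
) -> ModeratedTestResult:
    """Moderated two-group comparison over all events with >=2 covered
    samples per group.

    ``prior_df``/``prior_var`` override the moment-matched prior (0 recovers
    the ordinary pooled-variance t test; infinity collapses every posterior
    variance onto the prior variance).
    """
    rows = []
    for eid in table.events:
        va = table.covered_values(eid, group_a)
        vb = table.covered_values(eid, group_b)
        if va.size < 2 or vb.size < 2:
            continue
        na, nb = va.size, vb.size
        dfr = na + nb - 2
        s2 = (np.sum((va - va.mean()) ** 2) + np.sum((vb - vb.mean()) ** 2)) / dfr
        rows.append(
            (eid, na, nb, float(va.mean()), float(vb.mean()), float(s2), float(dfr))
        )
    if not rows:
        raise ValueError(
            "no event has >=2 covered samples in both groups; more replicates "
            "are required for the moderated test"
        )
    df = pd.DataFrame(
        rows, columns=["event_id", "n_a", "n_b", "mean_a", "mean_b", "s2", "df_residual"]
    ).set_index("event_id")
    dfr = df["df_residual"].to_numpy()
    s2 = df["s2"].to_numpy()
    if np.all(s2 <= 0):
        raise ValueError(
            "all events have zero residual variance; more replicates are required"
        )
    if prior_df is None or prior_var is None:
        d0_fit, s0_fit = _fit_f_dist(s2, dfr)
    else:
        d0_fit, s0_fit = float("nan"), float("nan")
    d0 = float(prior_df) if prior_df is not None else d0_fit
    s0_sq = float(prior_var) if prior_var is not None else s0_fit

    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.full_like(dfr, np.inf)
    else:
        s2_post = (d0 * s0_sq + dfr * s2) / (d0 + dfr)
        df_total = np.minimum(dfr + d0, float(np.sum(dfr)))
    stdev_unscaled = np.sqrt(1.0 / df["n_a"].to_numpy() + 1.0 / df["n_b"].to_numpy())
    delta = df["mean_a"].to_numpy() - df["mean_b"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = delta / (np.sqrt(s2_post) * stdev_unscaled)
    t_mod = np.where(np.isnan(t_mod) & (delta == 0), 0.0, t_mod)
    p = 2.0 * stats.t.sf(np.abs(t_mod), np.where(np.isfinite(df_total), df_total, 1e9))
    p = np.where(np.isnan(t_mod), 1.0, p)

    # B statistic: log posterior odds of differential inclusion; the prior
    # variance of the (unscaled) effect is clipped to effect standard
    # deviations between 0.1 and 4 residual standard deviations
    v0_lim = (0.01 / s0_sq, 16.0 / s0_sq) if s0_sq > 0 else (0.01, 16.0)
    v0 = _tmixture_vector(
        np.nan_to_num(t_mod), stdev_unscaled, df_total, prior_proportion, v0_lim
    )
    if not np.isfinite(v0) or v0 <= 0:
        v0 = 1.0 / s0_sq if s0_sq > 0 else 1.0
    r = (stdev_unscaled**2 + v0) / stdev_unscaled**2
    t2 = np.nan_to_num(t_mod) ** 2
    if math.isinf(d0) or d0 > 1e6:
        kernel = t2 * (1.0 - 1.0 / r) / 2.0
    else:
        fin_df = np.where(np.isfinite(df_total), df_total, 1e6)
        kernel = (1.0 + fin_df) / 2.0 * np.log((t2 + fin_df) / (t2 / r + fin_df))
    lods = math.log(prior_proportion / (1.0 - prior_proportion)) - np.log(r) / 2.0 + kernel

    df["delta"] = delta
    df["s2_post"] = s2_post
    df["t_mod"] = t_mod
    df["df_total"] = df_total
    df["p_value"] = p
    df["b_statistic"] = lods
    return ModeratedTestResult(table=df, d0=d0, s0_sq=s0_sq)


# -- neoblast-differential calling -------------------------------------------

@dataclass(frozen=True)
class DifferentialCall:
    event_id: str
    criteria_met: frozenset[str]
    p_value: float
    direction: str  # X1_INCLUDED or X1_EXCLUDED
    delta_psi: float  # Mean_X1 - Mean_diff
    b_statistic: float = float("nan")


def _criteria(
    x1: GroupSummary, diff: GroupSummary, *, ge_thresholds: bool = True
) -> frozenset[str]:
    """Evaluate the three differential criteria for one event.

    ``ge_thresholds`` applies |delta| >= 25 and |Mean_X1 - Mean80_diff| >= 20
    (the reading consistent with "large PSI differences"); flipping it applies
    the literal <=-form for audit.
    """
    delta = x1.mean - diff.mean
    a = abs(delta)
    met = set()

    def _cmp(value: float, threshold: float) -> bool:
        return value >= threshold if ge_thresholds else value <= threshold

    if _cmp(a, 25) and (
        x1.range < a / 2 or diff.range < a / 2 or x1.sd < a / 2 or diff.sd < a / 2
    ):
        met.add("Q1")
    if (
        diff.mean80 is not None
        and not math.isnan(diff.mean80)
        and _cmp(abs(x1.mean - diff.mean80), 20)
        and (x1.sd < a / 4 or diff.sd < a / 4)
    ):
        met.add("Q2")
    if (
        diff.n_covered >= 4
        and x1.n_covered >= 4
        and (
            (x1.min >= 98 and diff.max < 90)
            or (x1.max <= 2 and diff.min > 10)
            or (diff.min >= 98 and x1.max < 90)
            or (diff.max <= 2 and x1.min > 10)
        )
    ):
        met.add("Q3")
    return frozenset(met)


def call_neoblast_differential(
    table: InclusionTable,
    manifest: SampleManifest,
    alpha: float = 0.05,
    *,
    min_covered: int = 3,
    ge_thresholds: bool = True,
) -> tuple[list[DifferentialCall], pd.DataFrame]:
    """Call X1-vs-differentiated events and return (calls, skip report).

    Events need coverage in >= ``min_covered`` X1 samples and as many pooled
    differentiated samples; skipped events are listed with the reason.
    """
    x1 = manifest.samples_in("X1")
    diff = manifest.diff_samples()
    test = fit_moderated_test(table, x1, diff)
    calls: list[DifferentialCall] = []
    skipped: list[tuple[str, str]] = []
    for eid in table.events:
        vx1 = table.covered_values(eid, x1)
        vdiff = table.covered_values(eid, diff)
        if vx1.size < min_covered or vdiff.size < min_covered:
            skipped.append((eid, f"coverage {vx1.size} X1 / {vdiff.size} diff"))
            continue
        sx1 = summarize_group(vx1)
        sdiff = summarize_group(vdiff, reference_mean=sx1.mean)
        met = _criteria(sx1, sdiff, ge_thresholds=ge_thresholds)
        if not met:
            continue
        if eid not in test.events:
            skipped.append((eid, "too few samples for the moderated test"))
            continue
        p = float(test.table.loc[eid, "p_value"])
        if p >= alpha:
            continue
        delta = sx1.mean - sdiff.mean
        calls.append(
            DifferentialCall(
                event_id=eid,
                criteria_met=met,
                p_value=p,
                direction="X1_INCLUDED" if delta > 0 else "X1_EXCLUDED",
                delta_psi=delta,
                b_statistic=float(test.table.loc[eid, "b_statistic"]),
            )
        )
    skip_report = pd.DataFrame(skipped, columns=["event_id", "reason"])
    return calls, skip_report


def define_background(
    table: InclusionTable,
    manifest: SampleManifest,
    *,
    min_covered: int = 3,
) -> set[str]:
    """Non-differential ("AS_nonX1") background: alternatively spliced events
    with the same coverage gate, |Mean_X1 - Mean_diff| < 10 and moderated
    p >= 0.05."""
    x1 = manifest.samples_in("X1")
    diff = manifest.diff_samples()
    test = fit_moderated_test(table, x1, diff)
    background: set[str] = set()
    for eid in table.events:
        all_covered = table.covered_values(eid, list(table.samples))
        if not call_alternative(all_covered):
            continue
        vx1 = table.covered_values(eid, x1)
        vdiff = table.covered_values(eid, diff)
        if vx1.size < min_covered or vdiff.size < min_covered:
            continue
        if abs(vx1.mean() - vdiff.mean()) >= 10:
            continue
        if eid in test.events and float(test.table.loc[eid, "p_value"]) < 0.05:
            continue
        background.add(eid)
    return background


def kd_response(
    table_treated: InclusionTable,
    table_control: InclusionTable,
    differential_calls: Iterable[DifferentialCall],
    *,
    delta_threshold: float = 15.0,
) -> tuple[float, pd.DataFrame]:
    """Knockdown response of the differential events.

    Both tables carry one knockdown/control sample each (coverage assessed
    upstream under the strict regime).  An event responds when the
    treated-minus-control inclusion shift reaches ``delta_threshold`` in the
    direction of the X1 pattern (the sign of Mean_X1 - Mean_diff).  Returns
    the responsive fraction among eligible events plus the per-event table.
    """
    t_col = table_treated.samples[0]
    c_col = table_control.samples[0]
    rows = []
    for call in differential_calls:
        eid = call.event_id
        if eid not in table_treated.events or eid not in table_control.events:
            continue
        if not (
            bool(table_treated.covered.loc[eid, t_col])
            and bool(table_control.covered.loc[eid, c_col])
        ):
            continue
        pt = table_treated.values.loc[eid, t_col]
        pc = table_control.values.loc[eid, c_col]
        if pd.isna(pt) or pd.isna(pc):
            continue
        dpsi = float(pt - pc)
        responsive = abs(dpsi) >= delta_threshold and (
            math.copysign(1.0, dpsi) == math.copysign(1.0, call.delta_psi)
        )
        rows.append((eid, dpsi, call.delta_psi, responsive))
    if not rows:
        raise ValueError("no differential event is covered in both samples")
    out = pd.DataFrame(
        rows, columns=["event_id", "delta_psi_kd", "delta_psi_x1", "responsive"]
    ).set_index("event_id")
    return float(out["responsive"].mean()), out


def direction_association(
    delta_a: Mapping[str, float],
    delta_b: Mapping[str, float],
    alternative: str = "opposite",
    *,
    delta_threshold: float = 15.0,
) -> tuple[float, int, int]:
    """One-sided binomial test on the direction concordance of two shift sets.

    Pairs events present in both maps with |delta| >= ``delta_threshold`` in
    each; counts the pairs whose signs match the alternative ("opposite" or
    "same") and returns (exact upper-tail p under Binomial(n, 1/2), k, n).
    """
    if alternative not in ("opposite", "same"):
        raise ValueError("alternative must be 'opposite' or 'same'")
    shared = [
        e
        for e in delta_a
        if e in delta_b
        and abs(delta_a[e]) >= delta_threshold
        and abs(delta_b[e]) >= delta_threshold
    ]
    n = len(shared)
    if n == 0:
        raise ValueError("no shared events pass the |delta| threshold")
    k = 0
    for e in shared:
        opposite = (delta_a[e] > 0) != (delta_b[e] > 0)
        k += opposite if alternative == "opposite" else not opposite
    # exact tail sum P(X >= k), X ~ Binomial(n, 1/2)
    tail = sum(math.comb(n, i) for i in range(k, n + 1))
    return tail / 2.0**n, k, n
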