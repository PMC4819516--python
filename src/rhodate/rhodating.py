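"""Rho-statistic divergence dating with low-coverage aggregation.

The rho statistic of a clade relative to an ancestral node is the average
number of mutations accumulated on the lineage paths from the clade's tips up
to that node, per callable site.  With samples of very different callability
the per-sample counts are *pooled*: rho = (sum over tips of the mutation count
on the tip's path, restricted to sites callable in that tip) / (sum over tips
of the tip's callable site total L_s).  Restricting both numerator and
denominator to each tip's own callable sites makes the pooled estimator
unbiased under missing-at-random masking, and pooling (rather than averaging
per-tip rates) keeps the variance low for tips with few callable sites.

Dividing rho by a per-site per-year mutation rate converts it to years.  Three
confidence intervals are provided: rate-uncertainty propagation (divide the
point time by the rate bounds), a site bootstrap (resample all matrix columns,
re-count, take the 2.5/97.5 percentiles of the replicate times), and their
conservative multiplicative combination (apply the rate bounds to the
bootstrap endpoints).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import dendropy
import numpy as np

from .errors import ConfigError, DataError
from .phylo import HaploTree, SiteWeights
from .variants import GenotypeMatrix

#: Default per-site per-year mutation rate and its 95% bounds.
RATE_POINT_DEFAULT = 0.76e-9
RATE_LO_DEFAULT = 0.67e-9
RATE_HI_DEFAULT = 0.86e-9


@dataclass(frozen=True)
class MutationRate:
    """Point mutation rate per site per year with 95% bounds."""

    point: float = RATE_POINT_DEFAULT
    lo: float = RATE_LO_DEFAULT
    hi: float = RATE_HI_DEFAULT

    def __post_init__(self) -> None:
        if not 0 < self.lo <= self.point <= self.hi:
            raise ConfigError(
                f"mutation rate bounds must satisfy 0 < lo <= point <= hi, "
                f"got ({self.lo}, {self.point}, {self.hi})"
            )

    @classmethod
    def point_only(cls, point: float) -> "MutationRate":
        return cls(point=point, lo=point, hi=point)


@dataclass
class RhoEstimate:
    """Pooled rho for one clade relative to an ancestor node."""

    clade: frozenset[str]
    count: float            # pooled mutation count (weighted under bootstrap)
    total: float            # pooled callable-site total
    per_sample: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def rho_per_site(self) -> float:
        return self.count / self.total

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise DataError(f"clade {sorted(self.clade)}: pooled callable total is 0")
        if self.count < 0:
            raise DataError("negative mutation count")


@dataclass
class TimeEstimate:
    """Divergence time in years with three nested confidence intervals."""

    clade_a: frozenset[str]
    clade_b: frozenset[str]
    T: float
    ci_rate: tuple[float, float] | None = None
    ci_boot: tuple[float, float] | None = None
    ci_combined: tuple[float, float] | None = None
    boot_replicates: np.ndarray | None = None
    n_boot: int = 0

    def as_row(self) -> dict:
        ky = lambda x: None if x is None else round(x / 1000.0, 1)
        return {
            "clade_a": "+".join(sorted(self.clade_a)),
            "clade_b": "+".join(sorted(self.clade_b)),
            "T_ky": ky(self.T),
            "ci_rate_lo_ky": ky(self.ci_rate and self.ci_rate[0]),
            "ci_rate_hi_ky": ky(self.ci_rate and self.ci_rate[1]),
            "ci_boot_lo_ky": ky(self.ci_boot and self.ci_boot[0]),
            "ci_boot_hi_ky": ky(self.ci_boot and self.ci_boot[1]),
            "ci_combined_lo_ky": ky(self.ci_combined and self.ci_combined[0]),
            "ci_combined_hi_ky": ky(self.ci_combined and self.ci_combined[1]),
            "n_boot": self.n_boot,
        }


# ---------------------------------------------------------------------------
# rho and time
# ---------------------------------------------------------------------------


def _weighted_callable_totals(
    matrix: GenotypeMatrix, rows: list[int], weights: SiteWeights
) -> np.ndarray:
    vc = matrix.variant_callable()
    out = np.empty(len(rows))
    for k, i in enumerate(rows):
        bit = ((matrix.pattern_ids >> np.uint64(i)) & np.uint64(1)).astype(bool)
        out[k] = weights.variant[vc[i]].sum() + weights.pattern[bit].sum()
    return out


def _path_counts(
    htree: HaploTree, clade: list[str], ancestor: dendropy.Node,
    weights: SiteWeights,
) -> np.ndarray:
    """Per-tip weighted mutation counts on the path tip -> ancestor, restricted
    to sites callable in the tip."""
    matrix = htree.matrix
    vc = matrix.variant_callable()
    counts = np.empty(len(clade))
    for k, s in enumerate(clade):
        i = matrix.sample_index(s)
        cols: list[np.ndarray] = []
        for node in htree.path_to_ancestor(s, ancestor):
            mc = getattr(node, "mutation_cols", None)
            if mc is None:
                raise DataError("tree has no mutation mapping; run "
                                "map_mutations_parsimony first")
            cols.append(mc)
        allc = np.concatenate(cols) if cols else np.empty(0, dtype=int)
        allc = allc[vc[i, allc]] if len(allc) else allc
        counts[k] = weights.variant[allc].sum()
    return counts


def rho(
    htree: HaploTree,
    clade: Iterable[str],
    ancestor: dendropy.Node | Iterable[str] | None = None,
    weights: SiteWeights | None = None,
) -> RhoEstimate:
    """Pooled rho of ``clade`` relative to ``ancestor``.

    ``ancestor`` may be a tree node, a set of leaf labels (their MRCA is used),
    or None (MRCA of the clade itself).  Aggregation across samples is pooled:
    sum of per-tip path counts over sum of per-tip callable totals.
    """
    clade = sorted(clade)
    if not clade:
        raise DataError("empty clade")
    if ancestor is None:
        ancestor = htree.mrca(clade)
    elif not isinstance(ancestor, dendropy.Node):
        ancestor = htree.mrca(ancestor)
    w = weights or SiteWeights.unit(htree.matrix)
    counts = _path_counts(htree, clade, ancestor, w)
    rows = [htree.matrix.sample_index(s) for s in clade]
    totals = _weighted_callable_totals(htree.matrix, rows, w)
    if totals.sum() <= 0:
        raise DataError(f"clade {clade}: pooled callable total is 0")
    return RhoEstimate(
        clade=frozenset(clade),
        count=float(counts.sum()),
        total=float(totals.sum()),
        per_sample={s: (float(c), float(t)) for s, c, t in zip(clade, counts, totals)},
    )


def divergence_time(
    htree: HaploTree,
    clade_a: Iterable[str],
    clade_b: Iterable[str],
    rate: MutationRate,
    weights: SiteWeights | None = None,
) -> float:
    """Point divergence time in years between two clades.

    Both rho values are measured to the MRCA of the union, averaged, and
    divided by the point rate.
    """
    clade_a, clade_b = list(clade_a), list(clade_b)
    if not clade_a or not clade_b:
        raise DataError("empty clade")
    if rate.point <= 0:
        raise ConfigError("rate.point must be > 0")
    ancestor = htree.mrca(set(clade_a) | set(clade_b))
    ra = rho(htree, clade_a, ancestor, weights)
    rb = rho(htree, clade_b, ancestor, weights)
    return 0.5 * (ra.rho_per_site + rb.rho_per_site) / rate.point


def calibrate_rate(
    htree: HaploTree,
    ancient_tip: str,
    age_years: float,
    modern_tips: Iterable[str] | None = None,
) -> MutationRate:
    """Calibrate the per-site per-year rate from an ancient sample's branch
    shortening.

    The ancient lineage stopped accumulating mutations ``age_years`` ago, so
    the per-site deficit of its rho (to the ancestor it shares with the modern
    tips) relative to the modern tips' mean rho equals rate * age.  rho_modern
    is the arithmetic mean of the per-tip rho values.
    """
    if age_years <= 0:
        raise ConfigError("ancient tip age must be > 0")
    if modern_tips is None:
        modern_tips = [l for l in htree.leaf_labels() if l != ancient_tip]
    modern_tips = sorted(modern_tips)
    if not modern_tips:
        raise DataError("need at least one modern tip")
    ancestor = htree.mrca(set(modern_tips) | {ancient_tip})
    w = SiteWeights.unit(htree.matrix)
    r_anc = rho(htree, [ancient_tip], ancestor, w).rho_per_site
    per_tip = [rho(htree, [s], ancestor, w).rho_per_site for s in modern_tips]
    r_mod = float(np.mean(per_tip))
    if r_mod <= r_anc:
        raise DataError(
            f"modern rho ({r_mod:g}) <= ancient rho ({r_anc:g}): negative or "
            "zero rate; check rooting and the ancient tip's age"
        )
    return MutationRate.point_only((r_mod - r_anc) / age_years)


# ---------------------------------------------------------------------------
# Confidence intervals
# ---------------------------------------------------------------------------


def rate_ci_propagate(T: float, rate: MutationRate) -> tuple[float, float]:
    """Propagate the rate's 95% bounds to a time: a faster clock shortens the
    estimate, so lo = T * point/hi and hi = T * point/lo (same units as T)."""
    return T * rate.point / rate.hi, T * rate.point / rate.lo


def combine_ci(boot_ci: tuple[float, float], rate: MutationRate) -> tuple[float, float]:
    """Conservative multiplicative combination: apply the rate bounds to the
    bootstrap interval's endpoints."""
    lo, hi = boot_ci
    if lo > hi:
        raise ConfigError("bootstrap CI endpoints out of order")
    return lo * rate.point / rate.hi, hi * rate.point / rate.lo


def site_bootstrap_ci(
    htree: HaploTree,
    clade_a: Iterable[str],
    clade_b: Iterable[str],
    rate: MutationRate,
    n_reps: int = 100,
    seed: int = 0,
) -> tuple[tuple[float, float], np.ndarray]:
    """Site-bootstrap CI for the divergence time of two clades.

    All matrix columns (variant and invariant) are resampled with replacement;
    per replicate the mutation counting and rho/time computation are re-run on
    the fixed topology (per-site parsimony assignments do not depend on column
    multiplicity, so resampling reduces to reweighting).  The CI is the
    2.5/97.5 percentile pair (linear interpolation).  Deterministic given seed.
    """
    if n_reps < 2:
        raise ConfigError("n_reps must be >= 2")
    clade_a, clade_b = sorted(clade_a), sorted(clade_b)
    for cl in (clade_a, clade_b):
        if not htree.is_monophyletic(cl):
            raise DataError(f"clade {cl} is not monophyletic on the fixed topology")
    matrix = htree.matrix
    ancestor = htree.mrca(set(clade_a) | set(clade_b))

    # Precompute, per tip: callable mutation columns on its path, its callable
    # variant-site selector, and its pattern bit; replicates then only reweight.
    vc = matrix.variant_callable()
    tips = [(s, a) for s, a in
            [(s, "a") for s in clade_a] + [(s, "b") for s in clade_b]]
    path_cols, var_sel, pat_bit = {}, {}, {}
    for s, _ in tips:
        i = matrix.sample_index(s)
        cols = [getattr(nd, "mutation_cols") for nd in htree.path_to_ancestor(s, ancestor)]
        allc = np.concatenate(cols) if cols else np.empty(0, dtype=int)
        path_cols[s] = allc[vc[i, allc]] if len(allc) else allc
        var_sel[s] = vc[i]
        pat_bit[s] = ((matrix.pattern_ids >> np.uint64(i)) & np.uint64(1)).astype(bool)

    rng = np.random.default_rng(seed)
    reps = np.empty(n_reps)
    for r in range(n_reps):
        w = SiteWeights.bootstrap(matrix, rng)
        rhos = {}
        for group, clade in (("a", clade_a), ("b", clade_b)):
            cnt = sum(w.variant[path_cols[s]].sum() for s in clade)
            tot = sum(w.variant[var_sel[s]].sum() + w.pattern[pat_bit[s]].sum()
                      for s in clade)
            rhos[group] = cnt / tot
        reps[r] = 0.5 * (rhos["a"] + rhos["b"]) / rate.point
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return (float(lo), float(hi)), reps


def date_clade_pair(
    htree: HaploTree,
    clade_a: Iterable[str],
    clade_b: Iterable[str],
    rate: MutationRate,
    n_boot: int = 100,
    seed: int = 0,
) -> TimeEstimate:
    """Full dating of one clade pair: point time plus the three CIs.

    ``n_boot = 0`` skips the bootstrap (and the combined CI with it).
    """
    clade_a, clade_b = sorted(clade_a), sorted(clade_b)
    T = divergence_time(htree, clade_a, clade_b, rate)
    est = TimeEstimate(
        clade_a=frozenset(clade_a), clade_b=frozenset(clade_b), T=T,
        ci_rate=rate_ci_propagate(T, rate),
    )
    if n_boot:
        est.ci_boot, est.boot_replicates = site_bootstrap_ci(
            htree, clade_a, clade_b, rate, n_reps=n_boot, seed=seed
        )
        est.ci_combined = combine_ci(est.ci_boot, rate)
        est.n_boot = n_boot
    return est
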