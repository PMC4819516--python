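"""Synthetic Y-chromosome-style datasets with known ground truth.

The generator emulates the study design the dating pipeline targets: a fixed,
known genealogy (the Y chromosome does not recombine, so a single tree applies
to the whole chromosome) over two deeply diverged clades plus outgroups; an
infinite-sites mutation process at a per-site per-year rate over a universe of
~10 million callable sites; per-sample callable masks that drop sites
missing-completely-at-random to mimic low-coverage sequencing; optionally an
ancient tip of known age (for mutation-rate calibration by branch shortening)
and a matched panel of Y-STR loci evolving under a stepwise mutation model.

Mutations are Poisson per branch with mean ``mu * L * branch_years`` and are
placed on distinct uniformly chosen sites (infinite sites; a collision with the
universe size is an error, not a silent multi-hit).  All randomness flows from
a single seed; per-purpose substreams are spawned deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping

import json

import dendropy
import numpy as np
import pandas as pd

from . import treeio, variants
from .errors import ConfigError, InfiniteSitesError
from .strdating import STRPanel
from .variants import GenotypeMatrix

MU_DEFAULT = 0.76e-9            # per site per year
L_DEFAULT = 10_000_000          # callable site universe
STR_RATE_DEFAULT = 2.08e-3      # per locus per generation
GENERATION_YEARS_DEFAULT = 25.0
STR_BOUND_DEFAULT = 10          # reflecting boundary, repeat steps from root allele


@dataclass
class SimConfig:
    """Parameters of one synthetic dataset.

    tree_spec:
        Newick with branch lengths in years; tips are modern (age 0) unless
        listed in ``ancient_tips`` (label -> age in years).
    coverage:
        Callable fraction c_s in (0, 1], per sample (mapping) or shared scalar.
    """

    tree_spec: str
    mu: float = MU_DEFAULT
    L: int = L_DEFAULT
    coverage: Mapping[str, float] | float = 1.0
    ancient_tips: dict[str, float] = dc_field(default_factory=dict)
    str_loci: int = 10
    str_rate: float = STR_RATE_DEFAULT
    generation_years: float = GENERATION_YEARS_DEFAULT
    str_bound: int | None = STR_BOUND_DEFAULT
    str_root_allele: int = 20
    populations: dict[str, str] = dc_field(default_factory=dict)
    haplogroups: dict[str, str] = dc_field(default_factory=dict)
    seed: int = 0

    def coverage_of(self, sample: str) -> float:
        c = self.coverage[sample] if isinstance(self.coverage, Mapping) else self.coverage
        c = float(c)
        if not 0.0 < c <= 1.0:
            raise ConfigError(f"coverage for {sample} must be in (0, 1], got {c}")
        return c

    def validate(self) -> None:
        if self.mu < 0:
            raise ConfigError("mu must be >= 0")
        if self.L < 1:
            raise ConfigError("L must be >= 1")
        if self.generation_years <= 0:
            raise ConfigError("generation_years must be > 0")
        for tip, age in self.ancient_tips.items():
            if age < 0:
                raise ConfigError(f"ancient tip {tip} has negative age")


@dataclass
class GroundTruth:
    """The generating genealogy and everything derived from it.

    Branch keys are the frozenset of leaf labels below the branch; node ages
    are in years.
    """

    tree: dendropy.Tree
    ages: dict  # node -> age (years)
    branch_sites: dict[frozenset, np.ndarray]
    str_events: dict[frozenset, np.ndarray] | None = None

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def branch_counts(self) -> dict[frozenset, int]:
        return {k: len(v) for k, v in self.branch_sites.items()}

    def true_divergence(self, leaves_a, leaves_b) -> float:
        """Age (years) of the MRCA of the two leaf sets."""
        node = treeio.mrca_node(self.tree, set(leaves_a) | set(leaves_b))
        return self.ages[node]

    def derived_leafsets(self) -> tuple[np.ndarray, list[frozenset]]:
        """All mutated positions with the leaf set carrying each mutation."""
        pos, owner = [], []
        for leafset, sites in self.branch_sites.items():
            pos.extend(int(p) for p in sites)
            owner.extend([leafset] * len(sites))
        order = np.argsort(pos)
        return np.asarray(pos, dtype=np.int64)[order], [owner[i] for i in order]

    def write(self, newick_path: str | Path, json_path: str | Path) -> None:
        Path(newick_path).write_text(self.newick() + "\n")
        payload = {
            "branches": [
                {"leaves": sorted(k), "n_mutations": len(v),
                 "sites": [int(p) for p in v]}
                for k, v in sorted(self.branch_sites.items(), key=lambda kv: sorted(kv[0]))
            ],
            "node_ages": [
                {"leaves": sorted(treeio.clade_leafset(nd)), "age_years": age}
                for nd, age in self.ages.items()
            ],
        }
        if self.str_events is not None:
            payload["str_event_counts"] = [
                {"leaves": sorted(k), "events_per_locus": [int(x) for x in v]}
                for k, v in sorted(self.str_events.items(), key=lambda kv: sorted(kv[0]))
            ]
        Path(json_path).write_text(json.dumps(payload, indent=1))


@dataclass
class SimulatedSNVData:
    """In-memory result of :func:`simulate_snv_dataset` plus file writers."""

    matrix: GenotypeMatrix
    truth: GroundTruth
    panel: variants.SamplePanel
    config: SimConfig
    _ref: np.ndarray | None = None
    _alt: np.ndarray | None = None
    # site-exact mask bookkeeping: invariant-only pattern summary plus the
    # positions/mask columns of invisible (all-carriers-masked) mutations
    _inv_pattern_ids: np.ndarray | None = None
    _inv_pattern_counts: np.ndarray | None = None
    _dropped_positions: np.ndarray | None = None
    _dropped_masks: np.ndarray | None = None

    def write_vcf(self, path: str | Path, diploid: bool = False) -> None:
        variants.write_vcf(
            path, self.matrix.sample_ids, self.matrix.positions, self.matrix.calls,
            self.matrix.universe_size, contig=self.matrix.contig, diploid=diploid,
            ref_alleles=self._ref, alt_alleles=self._alt,
        )

    def write_masks(self, mask_dir: str | Path) -> dict[str, Path]:
        """Realize per-site masks consistent with the pattern summary and write
        one BED per sample.  Deterministic given the dataset seed."""
        mask_dir = Path(mask_dir)
        mask_dir.mkdir(parents=True, exist_ok=True)
        masks = self.realized_masks()
        out = {}
        for s in self.matrix.sample_ids:
            p = mask_dir / f"{s}.bed"
            variants.write_bed_mask(masks[s], p, self.matrix.contig)
            out[s] = p
        return out

    def realized_masks(self) -> dict[str, np.ndarray]:
        """Per-sample boolean callable masks over [1, L], site-exact.

        Every mutated position (visible or invisible) keeps the mask column it
        was simulated with; the unmutated positions receive the invariant
        pattern classes in a deterministic seed-derived arrangement (they are
        exchangeable, so any arrangement realizes the same joint law)."""
        m = self.matrix
        rng = np.random.default_rng(
            np.random.SeedSequence(self.config.seed).spawn(5)[4]
        )
        mutated = np.concatenate([m.positions, self._dropped_positions])
        inv_mask = np.ones(m.universe_size, dtype=bool)
        inv_mask[mutated - 1] = False
        inv_idx = np.flatnonzero(inv_mask)
        assignment = np.repeat(self._inv_pattern_ids, self._inv_pattern_counts)
        rng.shuffle(assignment)
        masks = {}
        vc = m.variant_callable()
        for i, s in enumerate(m.sample_ids):
            arr = np.zeros(m.universe_size, dtype=bool)
            arr[inv_idx] = (assignment >> np.uint64(i)) & np.uint64(1) == 1
            arr[m.positions - 1] = vc[i]
            arr[self._dropped_positions - 1] = self._dropped_masks[i]
            masks[s] = arr
        return masks

    def write_panel(self, path: str | Path) -> None:
        self.panel.write(path)

    def write_truth(self, newick_path: str | Path, json_path: str | Path) -> None:
        self.truth.write(newick_path, json_path)


def _invariant_patterns(
    rng: np.random.Generator, cov: np.ndarray, n_sites: int
) -> tuple[np.ndarray, np.ndarray]:
    """Joint callable-pattern counts for ``n_sites`` MCAR invariant sites.

    For <= 16 samples the exact multinomial over all 2^n product-Bernoulli
    patterns is drawn directly; for more samples, sites are drawn explicitly in
    chunks and summarized.  Both are exact realizations of per-site independent
    masking.
    """
    n = len(cov)
    if n <= 16:
        probs = np.array([1.0])
        for c in cov:
            probs = np.concatenate([probs * (1.0 - c), probs * c])
        counts = rng.multinomial(n_sites, probs)
        nz = np.flatnonzero(counts)
        return nz.astype(np.uint64), counts[nz].astype(np.int64)
    acc: dict[int, int] = {}
    remaining = n_sites
    chunk = 1_000_000
    while remaining > 0:
        k = min(chunk, remaining)
        bits = rng.random((n, k)) < cov[:, None]
        ids = np.zeros(k, dtype=np.uint64)
        for s in range(n):
            ids |= bits[s].astype(np.uint64) << np.uint64(s)
        pat, cnt = np.unique(ids, return_counts=True)
        for p, c in zip(pat, cnt):
            acc[int(p)] = acc.get(int(p), 0) + int(c)
        remaining -= k
    pats = np.array(sorted(acc), dtype=np.uint64)
    return pats, np.array([acc[int(p)] for p in pats], dtype=np.int64)


def simulate_snv_dataset(config: SimConfig) -> SimulatedSNVData:
    """Simulate haploid SNV genotypes, masks, and panel for one genealogy.

    Each branch receives Poisson(mu * L * branch_years) mutations on distinct
    uniformly chosen sites; a tip is derived at a site iff the site's mutation
    lies on its root path; each sample's callable mask drops sites independently
    with probability 1 - c_s, and masked genotypes are missing.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed).spawn(5)
    rng_mut = np.random.default_rng(ss[0])
    rng_mask = np.random.default_rng(ss[1])

    tree = treeio.parse_tree(config.tree_spec, rooted=True)
    samples = sorted(treeio.leaf_labels(tree))
    ages = treeio.node_ages(tree, config.ancient_tips)

    edges = []  # (leafset, branch_years)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        years = ages[node.parent_node] - ages[node]
        edges.append((treeio.clade_leafset(node), years))

    n_mut = rng_mut.poisson(np.array([config.mu * config.L * t for _, t in edges]))
    total = int(n_mut.sum())
    if total > config.L:
        raise InfiniteSitesError(
            f"{total} mutations exceed the {config.L}-site universe "
            "(infinite-sites violation); increase L"
        )
    sites = rng_mut.choice(config.L, size=total, replace=False) + 1

    branch_sites: dict[frozenset, np.ndarray] = {}
    row_of = {s: i for i, s in enumerate(samples)}
    calls = np.zeros((len(samples), total), dtype=np.int8)
    off = 0
    for (leafset, _), k in zip(edges, n_mut):
        chunk = np.sort(sites[off:off + int(k)])
        branch_sites[leafset] = chunk
        off += int(k)
    # rebuild columns in genome order
    positions, owners = GroundTruth(tree, ages, branch_sites).derived_leafsets()
    for col, leafset in enumerate(owners):
        for s in leafset:
            calls[row_of[s], col] = variants.DERIVED

    cov = np.array([config.coverage_of(s) for s in samples])
    mask_var = rng_mask.random((len(samples), len(positions))) < cov[:, None]
    calls[~mask_var] = variants.MISSING
    pat_inv, cnt_inv = _invariant_patterns(rng_mask, cov, config.L - len(positions))

    # mutations whose carriers are all masked are invisible: fold their mask
    # columns into the invariant summary (keeping their positional masks so
    # written BED files stay site-exact)
    visible = (calls == variants.DERIVED).any(axis=0)
    dropped_positions = positions[~visible]
    dropped_masks = mask_var[:, ~visible]
    pat, cnt = variants.merge_pattern_summaries(
        (pat_inv, cnt_inv), variants._pattern_summary(dropped_masks)
    )
    matrix = GenotypeMatrix(
        sample_ids=samples,
        positions=positions[visible],
        calls=calls[:, visible],
        universe_size=config.L,
        pattern_ids=pat,
        pattern_counts=cnt,
    )

    truth = GroundTruth(tree=tree, ages=ages, branch_sites=branch_sites)
    panel = variants.SamplePanel(pd.DataFrame({
        "sample_id": samples,
        "population": [config.populations.get(s, "SIM") for s in samples],
        "coverage_class": ["high" if cov[i] >= 0.99 else "low" for i in range(len(samples))],
        "haplogroup_truth": [config.haplogroups.get(s, "") for s in samples],
    }))

    rng_alleles = np.random.default_rng(ss[3])
    bases = np.array(list("ACGT"))
    ref_idx = rng_alleles.integers(0, 4, size=matrix.n_sites)
    alt_shift = rng_alleles.integers(1, 4, size=matrix.n_sites)
    ref = bases[ref_idx]
    alt = bases[(ref_idx + alt_shift) % 4]

    return SimulatedSNVData(matrix=matrix, truth=truth, panel=panel, config=config,
                            _ref=ref, _alt=alt,
                            _inv_pattern_ids=pat_inv, _inv_pattern_counts=cnt_inv,
                            _dropped_positions=dropped_positions,
                            _dropped_masks=dropped_masks)


def simulate_str_panel(config: SimConfig) -> tuple[STRPanel, GroundTruth]:
    """Evolve an STR panel along the genealogy under a symmetric stepwise model.

    Per branch and locus the number of mutation events is Poisson with mean
    ``str_rate * branch_years / generation_years``; each event moves the repeat
    length by +1 or -1 with equal probability.  If ``str_bound`` is set, alleles
    reflect at ``str_root_allele +/- str_bound`` (distances saturate there, the
    mechanism behind STR underestimation of deep divergences).
    """
    config.validate()
    if config.str_rate < 0:
        raise ConfigError("str_rate cannot be negative")
    ss = np.random.SeedSequence(config.seed).spawn(5)
    rng = np.random.default_rng(ss[2])

    tree = treeio.parse_tree(config.tree_spec, rooted=True)
    ages = treeio.node_ages(tree, config.ancient_tips)
    lo = hi = None
    if config.str_bound is not None:
        lo = config.str_root_allele - config.str_bound
        hi = config.str_root_allele + config.str_bound

    nloc = config.str_loci
    alleles: dict[dendropy.Node, np.ndarray] = {}
    events: dict[frozenset, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            alleles[node] = np.full(nloc, config.str_root_allele, dtype=np.int64)
            continue
        gens = (ages[node.parent_node] - ages[node]) / config.generation_years
        n_ev = rng.poisson(config.str_rate * gens, size=nloc)
        cur = alleles[node.parent_node].copy()
        for loc in range(nloc):
            for _ in range(int(n_ev[loc])):
                step = 1 if rng.random() < 0.5 else -1
                nxt = cur[loc] + step
                if lo is not None and (nxt < lo or nxt > hi):
                    nxt = cur[loc] - step  # reflect off the boundary
                cur[loc] = nxt
        alleles[node] = cur
        events[treeio.clade_leafset(node)] = n_ev

    samples = sorted(treeio.leaf_labels(tree))
    loci = [f"STR{k + 1}" for k in range(nloc)]
    lengths = pd.DataFrame(
        {s: alleles[lf] for lf in tree.leaf_node_iter() for s in [lf.taxon.label]},
    ).T.reindex(samples)
    lengths.columns = loci
    panel = STRPanel(
        lengths=lengths,
        rate_per_gen=config.str_rate,
        generation_years=config.generation_years,
    )
    truth = GroundTruth(tree=tree, ages=ages, branch_sites={}, str_events=events)
    return panel, truth


# ---------------------------------------------------------------------------
# Demo genealogies
# ---------------------------------------------------------------------------


def _pectinate(labels: list[str], crown: float) -> tuple[str, float]:
    """Newick for a ladder over modern tips, deepest coalescence at ``crown``."""
    if len(labels) == 1:
        return labels[0], 0.0
    n = len(labels)
    sub, age = labels[0], 0.0
    for k in range(1, n):
        t = crown * k / (n - 1)
        sub = f"({sub}:{t - age:g},{labels[k]}:{t:g})"
        age = t
    return sub, age


def two_clade_newick(
    n_a: int = 5,
    n_b: int = 5,
    split: float = 54_000.0,
    crown_a: float = 45_000.0,
    crown_b: float = 45_000.0,
    outgroup_age: float = 70_000.0,
    prefix_a: str = "AUS",
    prefix_b: str = "SAS",
    outgroup: str = "OUT1",
) -> str:
    """Two clades splitting at ``split`` years, rooted by an outgroup lineage.

    This is the study design the package is exercised on: two deeply diverged
    clades (by default ~54 ky, with ladder-like internal coalescences up to the
    crown ages) plus a single deeper outgroup for rooting.
    """
    if not 0 < crown_a < split or not 0 < crown_b < split or split >= outgroup_age:
        raise ConfigError("need 0 < crown < split < outgroup_age")
    a, _ = _pectinate([f"{prefix_a}{i + 1}" for i in range(n_a)], crown_a)
    b, _ = _pectinate([f"{prefix_b}{i + 1}" for i in range(n_b)], crown_b)
    ingroup = f"({a}:{split - crown_a:g},{b}:{split - crown_b:g})"
    return f"({ingroup}:{outgroup_age - split:g},{outgroup}:{outgroup_age:g});"


def demo_config(seed: int = 0, L: int = L_DEFAULT, low_coverage: float = 0.4,
                split: float = 54_000.0, **tree_kwargs) -> SimConfig:
    """The default demonstration dataset: 5+5 tips, mixed coverage classes
    (half of each clade fully callable, half low-coverage), one outgroup."""
    tree = two_clade_newick(split=split, **tree_kwargs)
    labels = sorted(treeio.leaf_labels(treeio.parse_tree(tree)))
    coverage = {}
    haplogroups = {}
    for lab in labels:
        if lab.startswith("OUT"):
            coverage[lab] = 1.0
            haplogroups[lab] = "OUT"
        else:
            idx = int(lab[3:])
            coverage[lab] = 1.0 if idx % 2 == 1 else low_coverage
            haplogroups[lab] = "C-AUS" if lab.startswith("AUS") else "C5-SAS"
    pops = {lab: ("AUS" if lab.startswith("AUS") else
                  "SAS" if lab.startswith("SAS") else "OUT") for lab in labels}
    return SimConfig(tree_spec=tree, L=L, coverage=coverage, seed=seed,
                     populations=pops, haplogroups=haplogroups)
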