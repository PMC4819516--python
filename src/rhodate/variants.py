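"""Haploid genotype matrices and their on-disk formats.

The central container is :class:`GenotypeMatrix`: an (n_samples x n_variant_sites)
matrix of haploid calls (0 = ancestral, 1 = derived, -1 = missing) over a site
universe of ``universe_size`` callable positions on a single contig.  Only variant
sites are stored explicitly.  Callability at the (vastly more numerous) invariant
sites is kept as *joint callable-pattern counts*: each invariant site contributes
one bitmask over samples (bit s set iff the site is inside sample s's callable
mask), and the matrix stores the distinct bitmasks with their multiplicities.
This compressed form is exact for every statistic the package needs — per-sample
callable totals L_s, pairwise shared-callable denominators, and site-bootstrap
resampling — while staying O(#patterns) instead of O(L) in memory.

File formats follow the field's conventions: VCF 4.x (single contig, biallelic
SNVs, REF = ancestral unless an AA INFO tag says otherwise), per-sample BED
callable masks (0-based half-open), and a tab-separated sample panel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

ANCESTRAL = 0
DERIVED = 1
MISSING = -1

_BASES = np.array(list("ACGT"))


def merge_pattern_summaries(*summaries) -> tuple[np.ndarray, np.ndarray]:
    """Merge sparse (pattern_ids, counts) summaries, summing multiplicities."""
    pat = np.concatenate([np.asarray(s[0], dtype=np.uint64) for s in summaries])
    cnt = np.concatenate([np.asarray(s[1], dtype=np.int64) for s in summaries])
    pat_u, inverse = np.unique(pat, return_inverse=True)
    cnt_u = np.zeros(len(pat_u), dtype=np.int64)
    np.add.at(cnt_u, inverse.ravel(), cnt)
    return pat_u, cnt_u


def _pattern_summary(masks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Compress boolean mask columns (n_samples x n_sites) into sparse
    (pattern_ids, counts) where bit s of a pattern is sample s's callability."""
    n = masks.shape[0]
    if n > 62:
        raise ConfigError("pattern summaries support at most 62 samples")
    ids = np.zeros(masks.shape[1], dtype=np.uint64)
    for s in range(n):
        ids |= masks[s].astype(np.uint64) << np.uint64(s)
    pat, cnt = np.unique(ids, return_counts=True)
    return pat, cnt.astype(np.int64)


@dataclass
class GenotypeMatrix:
    """Analysis-ready haploid genotype matrix with callability bookkeeping.

    Attributes
    ----------
    sample_ids:
        Ordered unique sample names (rows of ``calls``).
    positions:
        1-based variant-site coordinates, strictly increasing.
    calls:
        int8 array (n_samples, n_sites) in {0, 1, -1}.  A missing call means the
        site is outside the sample's callable mask (or was a filtered genotype).
    universe_size:
        Total number of sites in the accessibility universe (variant + invariant).
    pattern_ids, pattern_counts:
        Sparse joint-callability summary of the invariant sites (see module doc).
    sample_masks:
        Optional explicit per-sample boolean callable masks over the whole
        universe (index 0 <-> position 1).  Present when the matrix was read from
        VCF+BED files; required by :func:`merge_cohorts`.
    """

    sample_ids: list[str]
    positions: np.ndarray
    calls: np.ndarray
    universe_size: int
    pattern_ids: np.ndarray
    pattern_counts: np.ndarray
    contig: str = "Y"
    sample_masks: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("duplicate sample ids in genotype matrix")
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.positions)):
            raise DataError("calls shape does not match samples x positions")
        if int(self.pattern_counts.sum()) + len(self.positions) != self.universe_size:
            raise DataError(
                "invariant pattern counts + variant sites != universe size"
            )

    # -- basic accessors ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def sample_index(self, sample: str) -> int:
        try:
            return self.sample_ids.index(sample)
        except ValueError:
            raise DataError(f"unknown sample {sample!r}") from None

    def variant_callable(self) -> np.ndarray:
        """Boolean (n_samples, n_sites): call present (not missing)."""
        return self.calls != MISSING

    def _pattern_bit(self, i: int) -> np.ndarray:
        return ((self.pattern_ids >> np.uint64(i)) & np.uint64(1)).astype(bool)

    def callable_totals(self) -> np.ndarray:
        """Per-sample callable site count L_s over the whole universe."""
        var = self.variant_callable().sum(axis=1)
        inv = np.array(
            [self.pattern_counts[self._pattern_bit(i)].sum() for i in range(self.n_samples)]
        )
        return (var + inv).astype(np.int64)

    def shared_callable(self, i: int, j: int) -> int:
        """Number of universe sites callable in both samples i and j."""
        both_inv = self.pattern_counts[self._pattern_bit(i) & self._pattern_bit(j)].sum()
        vc = self.variant_callable()
        return int(both_inv + (vc[i] & vc[j]).sum())

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_explicit_masks(
        cls,
        sample_ids: Sequence[str],
        positions: Sequence[int],
        calls: np.ndarray,
        masks: Mapping[str, np.ndarray],
        universe_size: int,
        contig: str = "Y",
    ) -> "GenotypeMatrix":
        """Build a matrix from per-site boolean masks over [1, universe_size].

        ``masks[s][p-1]`` is True iff position p is callable in sample s.  Calls
        outside a sample's mask are forced to missing.
        """
        sample_ids = list(sample_ids)
        positions = np.asarray(positions, dtype=np.int64)
        calls = np.array(calls, dtype=np.int8)
        mask_arr = np.stack([np.asarray(masks[s], dtype=bool) for s in sample_ids])
        if mask_arr.shape[1] != universe_size:
            raise DataError("mask length does not match universe size")
        var_idx = positions - 1
        calls[~mask_arr[:, var_idx]] = MISSING
        inv = np.ones(universe_size, dtype=bool)
        inv[var_idx] = False
        pat, cnt = _pattern_summary(mask_arr[:, inv])
        return cls(
            sample_ids=sample_ids,
            positions=positions,
            calls=calls,
            universe_size=universe_size,
            pattern_ids=pat,
            pattern_counts=cnt,
            contig=contig,
            sample_masks={s: mask_arr[k] for k, s in enumerate(sample_ids)},
        )

    def drop_monomorphic(self) -> tuple["GenotypeMatrix", int]:
        """Remove sites with no observed derived call, folding their callability
        into the invariant-pattern summary.  Returns (new matrix, n_dropped)."""
        keep = (self.calls == DERIVED).any(axis=0)
        n_drop = int((~keep).sum())
        if n_drop == 0:
            return self, 0
        dropped_masks = self.variant_callable()[:, ~keep]
        pat_u, cnt_u = merge_pattern_summaries(
            (self.pattern_ids, self.pattern_counts), _pattern_summary(dropped_masks)
        )
        return (
            GenotypeMatrix(
                sample_ids=list(self.sample_ids),
                positions=self.positions[keep],
                calls=self.calls[:, keep],
                universe_size=self.universe_size,
                pattern_ids=pat_u,
                pattern_counts=cnt_u,
                contig=self.contig,
                sample_masks=self.sample_masks,
            ),
            n_drop,
        )


@dataclass
class SamplePanel:
    """Sample metadata: population label, coverage class, optional haplogroup."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "population", "coverage_class")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise DataError(f"panel is missing required column {col!r}")
        if self.table["sample_id"].duplicated().any():
            raise DataError("panel has duplicate sample ids")
        self.table = self.table.set_index("sample_id", drop=False)

    @classmethod
    def read(cls, path: str | Path) -> "SamplePanel":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def samples(self) -> list[str]:
        return list(self.table["sample_id"])

    def haplogroup_of(self, sample: str) -> str | None:
        if "haplogroup_truth" not in self.table.columns:
            return None
        val = self.table.loc[sample, "haplogroup_truth"]
        return None if pd.isna(val) else str(val)

    def samples_with_haplogroup(self, label: str) -> list[str]:
        if "haplogroup_truth" not in self.table.columns:
            return []
        t = self.table
        return list(t.loc[t["haplogroup_truth"] == label, "sample_id"])


@dataclass
class FilterLog:
    """Counts of records removed or degraded while reading genotypes."""

    n_kept: int = 0
    n_indel: int = 0
    n_multiallelic: int = 0
    n_het_missing: int = 0
    n_bad_ancestral: int = 0
    n_qual_filtered: int = 0
    n_monomorphic_dropped: int = 0
    warnings: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "kept_sites": self.n_kept,
            "dropped_indels": self.n_indel,
            "dropped_multiallelic": self.n_multiallelic,
            "het_calls_set_missing": self.n_het_missing,
            "dropped_bad_ancestral": self.n_bad_ancestral,
            "dropped_qual": self.n_qual_filtered,
            "dropped_monomorphic": self.n_monomorphic_dropped,
            "warnings": list(self.warnings),
        }


# ---------------------------------------------------------------------------
# BED masks
# ---------------------------------------------------------------------------


def read_bed_mask(path: str | Path, universe_size: int) -> np.ndarray:
    """Read a BED callable mask into a boolean array over [1, universe_size].

    BED intervals are 0-based half-open; index p-1 of the result corresponds to
    1-based position p.  An empty file yields an all-False mask.
    """
    mask = np.zeros(universe_size, dtype=bool)
    try:
        bed = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                          names=["chrom", "start", "end"], comment="#")
    except pd.errors.EmptyDataError:
        return mask
    for start, end in zip(bed["start"].astype(int), bed["end"].astype(int)):
        mask[max(start, 0):min(end, universe_size)] = True
    return mask


def write_bed_mask(mask: np.ndarray, path: str | Path, contig: str = "Y") -> None:
    """Write a boolean callable mask as merged BED intervals (0-based half-open)."""
    mask = np.asarray(mask, dtype=bool)
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    with open(path, "w") as fh:
        for a, b in zip(starts, ends):
            fh.write(f"{contig}\t{a}\t{b}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_vcf(
    path: str | Path,
    sample_ids: Sequence[str],
    positions: np.ndarray,
    calls: np.ndarray,
    universe_size: int,
    contig: str = "Y",
    diploid: bool = False,
    ref_alleles: Sequence[str] | None = None,
    alt_alleles: Sequence[str] | None = None,
) -> None:
    """Write haploid calls as a biallelic-SNV VCF (REF = ancestral).

    ``diploid=True`` emits homozygous-diploid genotypes (0/0, 1/1), the other
    dialect commonly seen in public Y-chromosome call sets.
    """
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={universe_size}>")
    header.add_line('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in sample_ids:
        header.add_sample(s)
    if ref_alleles is None:
        ref_alleles = ["A"] * len(positions)
    if alt_alleles is None:
        alt_alleles = ["G"] * len(positions)
    vf = pysam.VariantFile(str(path), "w", header=header)
    try:
        for k, pos in enumerate(positions):
            rec = vf.new_record(
                contig=contig, start=int(pos) - 1, stop=int(pos),
                alleles=(str(ref_alleles[k]), str(alt_alleles[k])),
            )
            rec.info["AA"] = str(ref_alleles[k])
            for i, s in enumerate(sample_ids):
                g = int(calls[i, k])
                if g == MISSING:
                    rec.samples[s]["GT"] = (None, None) if diploid else (None,)
                else:
                    rec.samples[s]["GT"] = (g, g) if diploid else (g,)
            vf.write(rec)
    finally:
        vf.close()


def read_genotypes(
    vcf_path: str | Path,
    mask_paths: Mapping[str, str | Path] | None,
    panel: SamplePanel | str | Path,
    universe_size: int | None = None,
    contig: str = "Y",
    min_qual: float | None = None,
) -> tuple[GenotypeMatrix, FilterLog]:
    """Read a VCF + per-sample BED masks + panel into a :class:`GenotypeMatrix`.

    Retains biallelic SNVs only; indels and multiallelic records are dropped and
    counted.  The ancestral state is REF unless a valid AA INFO tag names the ALT
    allele (then polarity is flipped).  Heterozygous diploid calls on a haploid
    chromosome are treated as missing (a genotype-quality proxy) and counted.
    Genotypes at sites outside a sample's mask are set to missing; samples absent
    from ``mask_paths`` are taken as fully callable.  Sites left without any
    derived call are dropped (their callability still counts toward L_s).
    """
    if not isinstance(panel, SamplePanel):
        panel = SamplePanel.read(panel)
    log = FilterLog()
    vf = pysam.VariantFile(str(vcf_path))
    samples = list(vf.header.samples)
    unknown = [s for s in samples if s not in set(panel.samples())]
    if unknown:
        raise DataError(f"VCF samples missing from panel: {unknown}")
    if universe_size is None:
        ctg = vf.header.contigs.get(contig)
        if ctg is None or not ctg.length:
            raise ConfigError(
                "universe_size not given and contig length absent from VCF header"
            )
        universe_size = ctg.length

    has_aa = "AA" in vf.header.info
    positions: list[int] = []
    columns: list[np.ndarray] = []
    for rec in vf:
        if rec.chrom != contig:
            raise DataError(f"unexpected contig {rec.chrom!r} (expected {contig!r})")
        alts = rec.alts or ()
        if len(alts) != 1:
            log.n_multiallelic += 1
            continue
        ref, alt = rec.ref, alts[0]
        if len(ref) != 1 or len(alt) != 1 or ref == "." or alt == ".":
            log.n_indel += 1
            continue
        if min_qual is not None and (rec.qual is None or rec.qual < min_qual):
            log.n_qual_filtered += 1
            continue
        flip = False
        aa = rec.info.get("AA") if has_aa else None
        if aa is not None:
            aa = str(aa).upper()
            if aa == alt.upper():
                flip = True
            elif aa != ref.upper():
                log.n_bad_ancestral += 1
                continue
        col = np.empty(len(samples), dtype=np.int8)
        for i, s in enumerate(samples):
            gt = rec.samples[s]["GT"]
            alleles = [a for a in (gt if isinstance(gt, tuple) else (gt,)) if a is not None]
            if not alleles:
                col[i] = MISSING
            elif len(set(alleles)) > 1:
                col[i] = MISSING
                log.n_het_missing += 1
            else:
                g = alleles[0]
                col[i] = (1 - g) if flip else g
        positions.append(rec.pos)
        columns.append(col)
    vf.close()

    calls = (
        np.stack(columns, axis=1) if columns else np.zeros((len(samples), 0), dtype=np.int8)
    )
    masks: dict[str, np.ndarray] = {}
    for s in samples:
        if mask_paths is not None and s in mask_paths:
            m = read_bed_mask(mask_paths[s], universe_size)
            if not m.any():
                msg = f"sample {s}: empty callable mask, all calls missing (L_s = 0)"
                log.warnings.append(msg)
                warnings.warn(msg, stacklevel=2)
        else:
            m = np.ones(universe_size, dtype=bool)
        masks[s] = m

    matrix = GenotypeMatrix.from_explicit_masks(
        samples, positions, calls, masks, universe_size, contig=contig
    )
    matrix, n_mono = matrix.drop_monomorphic()
    log.n_monomorphic_dropped = n_mono
    log.n_kept = matrix.n_sites
    logger.info(
        "read %d variant sites (%d indel, %d multiallelic, %d het->missing, "
        "%d monomorphic dropped)",
        log.n_kept, log.n_indel, log.n_multiallelic, log.n_het_missing, n_mono,
    )
    return matrix, log


def write_matrix(
    matrix: GenotypeMatrix,
    vcf_path: str | Path,
    mask_dir: str | Path | None = None,
    diploid: bool = False,
) -> None:
    """Write a matrix back to VCF (+ BED masks if positional masks are present)."""
    write_vcf(
        vcf_path, matrix.sample_ids, matrix.positions, matrix.calls,
        matrix.universe_size, contig=matrix.contig, diploid=diploid,
    )
    if mask_dir is not None:
        if matrix.sample_masks is None:
            raise DataError("matrix carries no positional masks to write")
        mask_dir = Path(mask_dir)
        mask_dir.mkdir(parents=True, exist_ok=True)
        for s in matrix.sample_ids:
            write_bed_mask(matrix.sample_masks[s], mask_dir / f"{s}.bed", matrix.contig)


def merge_cohorts(*matrices: GenotypeMatrix) -> GenotypeMatrix:
    """Union genotype matrices over disjoint sample sets on a shared coordinate
    system.

    At a position that is variant in some cohort but absent from another, a
    sample of the latter is called ancestral if the position is inside its
    callable mask (reference-implied) and missing otherwise.  Requires
    positional masks on every input (matrices read from VCF+BED carry them).
    """
    if not matrices:
        raise ConfigError("merge_cohorts needs at least one matrix")
    if len(matrices) == 1:
        return matrices[0]
    universe = matrices[0].universe_size
    contig = matrices[0].contig
    all_samples: list[str] = []
    for m in matrices:
        if m.universe_size != universe or m.contig != contig:
            raise DataError("cohorts disagree on contig or universe size")
        if m.sample_masks is None:
            raise DataError(
                "merge requires positional masks; round-trip simulated matrices "
                "through write_matrix/read_genotypes first"
            )
        all_samples.extend(m.sample_ids)
    if len(set(all_samples)) != len(all_samples):
        dupes = sorted({s for s in all_samples if all_samples.count(s) > 1})
        raise DataError(f"duplicate sample ids across cohorts: {dupes}")

    union_pos = np.unique(np.concatenate([m.positions for m in matrices]))
    calls = np.empty((len(all_samples), len(union_pos)), dtype=np.int8)
    masks: dict[str, np.ndarray] = {}
    row = 0
    for m in matrices:
        pos_to_col = {int(p): k for k, p in enumerate(m.positions)}
        for i, s in enumerate(m.sample_ids):
            smask = m.sample_masks[s]
            for k, p in enumerate(union_pos):
                col = pos_to_col.get(int(p))
                if col is not None:
                    calls[row, k] = m.calls[i, col]
                else:
                    calls[row, k] = ANCESTRAL if smask[p - 1] else MISSING
            masks[s] = smask
            row += 1
    merged = GenotypeMatrix.from_explicit_masks(
        all_samples, union_pos, calls, masks, universe, contig=contig
    )
    merged, _ = merged.drop_monomorphic()
    return merged
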