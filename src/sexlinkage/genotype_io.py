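"""Genotype, tag, sample-sheet and alignment-hit I/O plus locus/hit filters.

Genotype calls are stored as an int8 matrix (loci x samples) with codes
0 = hom-ref, 1 = het, 2 = hom-alt and ``MISSING`` (-1) for no-calls.
On-disk formats are VCF v4.2 (GT only) and a plain TSV dialect
(tab-separated, '#'-prefixed header row, ``NA`` for missing).  All
readers tolerate gzip-compressed input.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

#: column names of 12-column BLAST tabular output (outfmt 6)
BLAST6_COLUMNS = [
    "query_id",
    "subject_id",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotype calls for loci x samples."""

    loci: np.ndarray
    samples: np.ndarray
    calls: np.ndarray  # int8, shape (n_loci, n_samples)

    def __post_init__(self) -> None:
        self.loci = np.asarray(self.loci, dtype=object)
        self.samples = np.asarray(self.samples, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.loci), len(self.samples)):
            raise ValueError("calls shape does not match loci/samples")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("duplicate locus identifiers")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")
        bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype calls must be in {0, 1, 2, MISSING}")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset_loci(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.loci[keep], self.samples, self.calls[keep])

    def subset_samples(self, sample_ids: Iterable[str]) -> "GenotypeMatrix":
        sample_ids = list(sample_ids)
        idx = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        cols = [idx[s] for s in sample_ids]
        return GenotypeMatrix(self.loci, np.array(sample_ids, dtype=object), self.calls[:, cols])


@dataclass
class TagPresenceMatrix:
    """RADtag presence/absence (1/0) for tags x samples."""

    tags: np.ndarray
    samples: np.ndarray
    present: np.ndarray  # uint8, shape (n_tags, n_samples)

    def __post_init__(self) -> None:
        self.tags = np.asarray(self.tags, dtype=object)
        self.samples = np.asarray(self.samples, dtype=object)
        self.present = np.asarray(self.present, dtype=np.uint8)
        if self.present.shape != (len(self.tags), len(self.samples)):
            raise ValueError("present shape does not match tags/samples")
        if not np.isin(self.present, (0, 1)).all():
            raise ValueError("presence matrix must be 0/1")

    def subset_samples(self, sample_ids: Iterable[str]) -> "TagPresenceMatrix":
        sample_ids = list(sample_ids)
        idx = {s: i for i, s in enumerate(self.samples)}
        cols = [idx[s] for s in sample_ids]
        return TagPresenceMatrix(self.tags, np.array(sample_ids, dtype=object), self.present[:, cols])


@dataclass
class SampleSheet:
    """Phenotypic sex labels, one row per sample (sex in {M, F})."""

    sample_id: np.ndarray
    sex: np.ndarray

    def __post_init__(self) -> None:
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        self.sex = np.asarray(self.sex, dtype=object)
        if len(self.sample_id) != len(self.sex):
            raise ValueError("sample_id and sex must be equal length")
        if len(set(self.sample_id)) != len(self.sample_id):
            raise ValueError("duplicate sample identifiers in sheet")
        bad = set(self.sex) - {"M", "F"}
        if bad:
            raise ValueError(f"unknown sex token(s): {sorted(bad)}")

    def sex_of(self, samples: Iterable[str]) -> np.ndarray:
        lookup = dict(zip(self.sample_id, self.sex))
        missing = [s for s in samples if s not in lookup]
        if missing:
            raise KeyError(f"sample(s) absent from sample sheet: {missing}")
        return np.array([lookup[s] for s in samples], dtype=object)

    def male_mask(self, samples: Iterable[str]) -> np.ndarray:
        return self.sex_of(samples) == "M"

    def relabelled(self, new_sex: Iterable[str]) -> "SampleSheet":
        return SampleSheet(self.sample_id.copy(), np.asarray(list(new_sex), dtype=object))


@dataclass
class FilterParams:
    """Locus retention thresholds applied before sex-linkage screening.

    A SNP is retained when it is genotyped in at least
    ``min_presence_per_sex`` of males AND of females, its pooled minor
    allele frequency is >= ``min_maf``, and its observed heterozygosity
    is <= ``max_obs_het`` (the latter removes over-merged paralogous
    stacks, which look like excessively heterozygous loci).
    """

    min_presence_per_sex: float = 0.75
    min_maf: float = 0.05
    max_obs_het: float = 0.75

    def __post_init__(self) -> None:
        for name in ("min_presence_per_sex", "min_maf", "max_obs_het"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class AlignmentFilterParams:
    """Best-hit acceptance rule for BLAST-style tabular alignments.

    A query's best hit is kept only if its e-value is strictly below
    ``max_evalue`` and, when other hits exist, at least
    ``min_next_hit_ratio_orders`` orders of magnitude below the
    second-best e-value (guards against repetitive-genome ambiguity).
    """

    max_evalue: float = 1e-20
    min_next_hit_ratio_orders: float = 5.0

    def __post_init__(self) -> None:
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be > 0")
        if self.min_next_hit_ratio_orders < 0:
            raise ValueError("min_next_hit_ratio_orders must be >= 0")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def write_genotypes_tsv(gm: GenotypeMatrix, path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("#locus_id\t" + "\t".join(map(str, gm.samples)) + "\n")
        for locus, row in zip(gm.loci, gm.calls):
            cells = ["NA" if c == MISSING else str(int(c)) for c in row]
            fh.write(str(locus) + "\t" + "\t".join(cells) + "\n")


def read_genotypes_tsv(path) -> GenotypeMatrix:
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").lstrip("#").split("\t")
        samples = header[1:]
        loci, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            loci.append(parts[0])
            rows.append([MISSING if c == "NA" else int(c) for c in parts[1:]])
    return GenotypeMatrix(np.array(loci, dtype=object), np.array(samples, dtype=object), np.array(rows, dtype=np.int8))


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 with one biallelic SNP per locus (GT only)."""
    gt_strings = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=rad>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(map(str, gm.samples)) + "\n")
        for i, (locus, row) in enumerate(zip(gm.loci, gm.calls), start=1):
            gts = "\t".join(gt_strings[int(c)] for c in row)
            fh.write(f"rad\t{i}\t{locus}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF; multiallelic records are
    dropped with a logged count."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = np.array(vcf.samples, dtype=object)
    loci, rows = [], []
    n_multi = 0
    for i, v in enumerate(vcf):
        if len(v.ALT) > 1:
            n_multi += 1
            continue
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        gt = np.asarray(v.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        loci.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
        rows.append(gt)
    vcf.close()
    if n_multi:
        logger.warning("dropped %d multiallelic VCF record(s)", n_multi)
    return GenotypeMatrix(np.array(loci, dtype=object), samples, np.array(rows, dtype=np.int8))


def read_genotypes(path, format: str = "tsv") -> GenotypeMatrix:
    if format == "tsv":
        return read_genotypes_tsv(path)
    if format == "vcf":
        return read_vcf(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("#sample_id\tsex\n")
        for s, x in zip(sheet.sample_id, sheet.sex):
            fh.write(f"{s}\t{x}\n")


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", comment=None, header=0, dtype=str)
    df.columns = [c.lstrip("#") for c in df.columns]
    if not {"sample_id", "sex"} <= set(df.columns):
        raise ValueError("sample sheet needs columns sample_id and sex")
    return SampleSheet(df["sample_id"].to_numpy(dtype=object), df["sex"].to_numpy(dtype=object))


def write_tag_presence(tags: TagPresenceMatrix, path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("#tag_id\t" + "\t".join(map(str, tags.samples)) + "\n")
        for tag, row in zip(tags.tags, tags.present):
            fh.write(str(tag) + "\t" + "\t".join(str(int(c)) for c in row) + "\n")


def read_tag_presence(path) -> TagPresenceMatrix:
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").lstrip("#").split("\t")
        samples = header[1:]
        tags, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            tags.append(parts[0])
            rows.append([int(c) for c in parts[1:]])
    return TagPresenceMatrix(np.array(tags, dtype=object), np.array(samples, dtype=object), np.array(rows, dtype=np.uint8))


def check_samples_in_sheet(gm: GenotypeMatrix, sheet: SampleSheet) -> None:
    """Raise KeyError naming any matrix sample absent from the sheet."""
    sheet.sex_of(gm.samples)


def read_alignment_hits(path) -> pd.DataFrame:
    """Read 12-column BLAST tabular (outfmt 6) hits.

    Raises ValueError naming the first malformed line.
    """
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(f"malformed alignment line {lineno}: expected 12 columns, got {len(parts)}")
            try:
                rows.append(
                    (
                        parts[0],
                        parts[1],
                        float(parts[2]),
                        int(parts[3]),
                        int(parts[4]),
                        int(parts[5]),
                        int(parts[6]),
                        int(parts[7]),
                        int(parts[8]),
                        int(parts[9]),
                        float(parts[10]),
                        float(parts[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"malformed alignment line {lineno}: {exc}") from None
    df = pd.DataFrame(rows, columns=BLAST6_COLUMNS)
    if (df["evalue"] < 0).any():
        raise ValueError("negative e-value in alignment hits")
    return df


def write_alignment_hits(hits: pd.DataFrame, path) -> None:
    hits.to_csv(path, sep="\t", header=False, index=False, columns=BLAST6_COLUMNS)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def locus_filter_stats(gm: GenotypeMatrix, sheet: SampleSheet) -> pd.DataFrame:
    """Per-locus call rates by sex, pooled minor-allele frequency and
    observed heterozygosity (computed over non-missing calls)."""
    male = sheet.male_mask(gm.samples)
    female = ~male
    calls = gm.calls
    nonmiss = calls != MISSING

    with np.errstate(invalid="ignore", divide="ignore"):
        presence_m = nonmiss[:, male].mean(axis=1) if male.any() else np.zeros(gm.n_loci)
        presence_f = nonmiss[:, female].mean(axis=1) if female.any() else np.zeros(gm.n_loci)
        alt_counts = np.where(nonmiss, calls, 0).sum(axis=1)
        n_called = nonmiss.sum(axis=1)
        alt_freq = np.where(n_called > 0, alt_counts / (2.0 * np.maximum(n_called, 1)), np.nan)
        maf = np.minimum(alt_freq, 1.0 - alt_freq)
        n_het = (calls == 1).sum(axis=1)
        obs_het = np.where(n_called > 0, n_het / np.maximum(n_called, 1), np.nan)

    return pd.DataFrame(
        {
            "locus_id": gm.loci,
            "presence_m": presence_m,
            "presence_f": presence_f,
            "maf": maf,
            "obs_het": obs_het,
        }
    )


def filter_loci(gm: GenotypeMatrix, sheet: SampleSheet, params: FilterParams | None = None) -> GenotypeMatrix:
    """Apply the presence / MAF / heterozygosity locus filters.

    Retention thresholds stated as minima are read inclusively
    (``>=``); the heterozygosity ceiling is ``<=``.  Removal counts per
    rule are logged.  Note that when the heterogametic sex makes up
    more than ``max_obs_het`` of the samples, fully sex-linked loci
    (heterozygous in every heterogametic individual) can be removed by
    the heterozygosity rule.
    """
    params = params or FilterParams()
    male = sheet.male_mask(gm.samples)
    if not male.any() or male.all():
        raise ValueError("both sexes must be present for locus filtering")
    stats = locus_filter_stats(gm, sheet)

    ok_presence = (stats["presence_m"].to_numpy() >= params.min_presence_per_sex) & (
        stats["presence_f"].to_numpy() >= params.min_presence_per_sex
    )
    maf = stats["maf"].to_numpy()
    ok_maf = np.nan_to_num(maf, nan=-1.0) >= params.min_maf
    het = stats["obs_het"].to_numpy()
    ok_het = np.nan_to_num(het, nan=2.0) <= params.max_obs_het
    keep = ok_presence & ok_maf & ok_het

    logger.info(
        "locus filter: %d/%d retained (removed: presence %d, maf %d, het %d)",
        int(keep.sum()),
        gm.n_loci,
        int((~ok_presence).sum()),
        int((~ok_maf).sum()),
        int((~ok_het).sum()),
    )
    if not keep.any():
        logger.warning("locus filter removed every locus")
    return gm.subset_loci(keep)


def filter_alignment_hits(hits: pd.DataFrame, params: AlignmentFilterParams | None = None) -> pd.DataFrame:
    """Retain at most one (best) hit per query.

    The best hit (lowest e-value, ties broken by bit score) survives
    iff e-value < ``max_evalue`` and either no other hit exists or the
    second-best e-value is at least ``10**min_next_hit_ratio_orders``
    times larger.
    """
    params = params or AlignmentFilterParams()
    if hits.empty:
        return hits.iloc[0:0]
    kept = []
    ratio = 10.0 ** params.min_next_hit_ratio_orders
    for _, grp in hits.groupby("query_id", sort=False):
        grp = grp.sort_values(["evalue", "bitscore"], ascending=[True, False])
        best = grp.iloc[0]
        if not best["evalue"] < params.max_evalue:
            continue
        if len(grp) > 1:
            second = grp.iloc[1]["evalue"]
            if not second >= best["evalue"] * ratio:
                continue
        kept.append(best)
    if not kept:
        return hits.iloc[0:0]
    return pd.DataFrame(kept).reset_index(drop=True)


def read_scaffold_map(path) -> dict[str, str]:
    """Two-column TSV mapping scaffold id -> chromosome token."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=["scaffold", "chromosome"], dtype=str)
    return dict(zip(df["scaffold"], df["chromosome"]))
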