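"""Sex-chromosome identification against a random-subset alignment null.

Validated sex-linked markers are located on chromosome-assigned
scaffolds via their filtered best alignment hits.  Because false
positives, mis-mappings and translocations inflate per-chromosome
counts, the observed count is compared with the alignment counts of
random marker subsets of the same size drawn from the full catalogue:
a chromosome is identified as the sex chromosome only when it gathers
at least ``min_markers_on_chrom`` sex-linked markers AND strictly more
than the chosen percentile of its random-subset null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class AssignmentConfig:
    n_random_subsets: int = 1000
    percentile: float = 99.0
    min_markers_on_chrom: int = 10
    seed: int = 0
    with_replacement: bool = False

    def __post_init__(self) -> None:
        if self.min_markers_on_chrom < 1:
            raise ValueError("min_markers_on_chrom must be >= 1")
        if self.n_random_subsets < 1:
            raise ValueError("n_random_subsets must be >= 1")


def _chromosome_of_markers(
    marker_ids,
    filtered_hits: pd.DataFrame,
    scaffold_map: dict[str, str],
) -> tuple[dict[str, str], int, int]:
    """Chromosome per marker via its retained best hit.  Returns the
    mapping plus counts of unaligned and unplaced markers."""
    hit_scaffold = dict(zip(filtered_hits["query_id"], filtered_hits["subject_id"]))
    chrom_of: dict[str, str] = {}
    n_unaligned = n_unplaced = 0
    for m in marker_ids:
        scaf = hit_scaffold.get(m)
        if scaf is None:
            n_unaligned += 1
            continue
        chrom = scaffold_map.get(scaf)
        if chrom is None:
            n_unplaced += 1
            continue
        chrom_of[m] = chrom
    return chrom_of, n_unaligned, n_unplaced


def assign_markers(
    marker_ids,
    filtered_hits: pd.DataFrame,
    scaffold_map: dict[str, str],
) -> tuple[dict[str, int], int, int]:
    """Per-chromosome counts of markers, each contributing to at most
    one chromosome (its retained best hit).  Markers without a
    retained hit are counted as unaligned; hits to scaffolds absent
    from the map as unplaced (warned)."""
    chrom_of, n_unaligned, n_unplaced = _chromosome_of_markers(marker_ids, filtered_hits, scaffold_map)
    if n_unplaced:
        logger.warning("%d marker hit(s) to scaffolds absent from the chromosome map", n_unplaced)
    counts: dict[str, int] = {}
    for chrom in sorted(set(scaffold_map.values())):
        counts[chrom] = 0
    for chrom in chrom_of.values():
        counts[chrom] = counts.get(chrom, 0) + 1
    return counts, n_unaligned, n_unplaced


def random_subset_null(
    catalogue_ids,
    filtered_hits: pd.DataFrame,
    scaffold_map: dict[str, str],
    set_size: int,
    cfg: AssignmentConfig | None = None,
) -> dict[str, np.ndarray]:
    """Per-chromosome null series of aligned counts for random marker
    subsets of ``set_size`` drawn from the catalogue (without
    replacement within each replicate by default)."""
    cfg = cfg or AssignmentConfig()
    catalogue_ids = np.asarray(list(catalogue_ids), dtype=object)
    if set_size > catalogue_ids.size:
        raise ValueError(f"set_size {set_size} exceeds catalogue size {catalogue_ids.size}")
    chroms = sorted(set(scaffold_map.values()))
    chrom_index = {c: i for i, c in enumerate(chroms)}
    chrom_of, _, _ = _chromosome_of_markers(catalogue_ids, filtered_hits, scaffold_map)
    code = np.array([chrom_index.get(chrom_of.get(m), -1) for m in catalogue_ids], dtype=np.int64)

    rng = np.random.default_rng(cfg.seed)
    null = np.zeros((cfg.n_random_subsets, len(chroms)), dtype=np.int64)
    n = catalogue_ids.size
    for r in range(cfg.n_random_subsets):
        pick = rng.choice(n, size=set_size, replace=cfg.with_replacement)
        picked = code[pick]
        picked = picked[picked >= 0]
        null[r] = np.bincount(picked, minlength=len(chroms))
    return {c: null[:, i] for c, i in chrom_index.items()}


@dataclass
class ChromAssignment:
    """Outcome of sex-chromosome identification."""

    observed: dict[str, int]
    null_threshold: dict[str, float]
    passing: list[str]
    identified: str | None
    ambiguous: bool
    n_unaligned: int = 0
    n_unplaced: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chromosome": list(self.observed),
                "observed": list(self.observed.values()),
                "null_threshold": [self.null_threshold[c] for c in self.observed],
                "passed": [c in self.passing for c in self.observed],
            }
        )


def identify_sex_chromosome(
    counts: dict[str, int],
    null: dict[str, np.ndarray],
    cfg: AssignmentConfig | None = None,
    n_unaligned: int = 0,
    n_unplaced: int = 0,
) -> ChromAssignment:
    """Apply the marker floor and the percentile rule per chromosome.

    A chromosome passes iff its observed count >= the floor AND
    strictly exceeds the percentile of its null series.  If several
    pass, all are reported and the result is flagged ambiguous rather
    than forced unique.
    """
    cfg = cfg or AssignmentConfig()
    if set(counts) != set(null):
        raise ValueError("counts and null must cover identical chromosome sets")
    thresholds = {c: float(np.percentile(null[c], cfg.percentile)) for c in counts}
    passing = [
        c for c in counts if counts[c] >= cfg.min_markers_on_chrom and counts[c] > thresholds[c]
    ]
    identified = passing[0] if len(passing) == 1 else None
    if len(passing) > 1:
        logger.warning("multiple chromosomes pass identification: %s", passing)
    return ChromAssignment(
        observed=dict(counts),
        null_threshold=thresholds,
        passing=sorted(passing),
        identified=identified,
        ambiguous=len(passing) > 1,
        n_unaligned=n_unaligned,
        n_unplaced=n_unplaced,
    )
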