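"""Sex-permutation empirical nulls and the subsampling diagnostics.

Any screen for sex linkage yields false positives whose number depends
on sample size, sex skew and dataset properties, so an observed marker
count is only credible against an empirical null: sex labels are
permuted across samples (preserving the M/F counts), all six screens
are re-run per permutation, and the observed count must strictly
exceed the chosen percentile of the resulting distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sexlinkage.genotype_io import GenotypeMatrix, SampleSheet, TagPresenceMatrix
from sexlinkage.screens import ORIENTATIONS, ScreenParams, screen_counts_batch
from sexlinkage.simulate import SamplingDesign, TruthLabels

logger = logging.getLogger(__name__)

SCREEN_KEYS = [(a, o) for a in ("freq", "het", "sex_limited") for o in ORIENTATIONS]


@dataclass
class PermutationConfig:
    n_permutations: int = 1000
    percentile: float = 99.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0.0 < self.percentile < 100.0:
            raise ValueError("percentile must be in (0, 100)")


@dataclass
class EmpiricalNull:
    """Null marker-count series per screen plus the observed counts.

    ``threshold`` is the stated percentile of each series
    (linear-interpolation definition; the exact-rank 'higher' rule is
    used instead when the permutation count cannot resolve the
    percentile, with a warning).
    """

    counts: dict[tuple[str, str], np.ndarray]
    observed: dict[tuple[str, str], int]
    percentile: float
    n_permutations: int

    def threshold(self, key: tuple[str, str]) -> float:
        series = self.counts[key]
        if self.n_permutations * (1.0 - self.percentile / 100.0) < 1.0:
            return float(np.percentile(series, self.percentile, method="higher"))
        return float(np.percentile(series, self.percentile))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "approach": a,
                "orientation": o,
                "observed": self.observed[(a, o)],
                "null_mean": float(self.counts[(a, o)].mean()),
                "null_max": int(self.counts[(a, o)].max()),
                "threshold": self.threshold((a, o)),
            }
            for (a, o) in self.counts
        ]
        return pd.DataFrame(rows)


def _permutation_masks(male: np.ndarray, n_permutations: int, seed: int) -> np.ndarray:
    """(samples x n_permutations) male-mask matrix; each column is a
    label permutation (shuffle without replacement, M/F counts kept).
    Each permutation uses an independent child seed of the master."""
    children = np.random.SeedSequence(seed).spawn(n_permutations)
    S = male.size
    masks = np.empty((S, n_permutations), dtype=np.float32)
    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        masks[:, k] = male[rng.permutation(S)]
    return masks


def build_null(
    gm: GenotypeMatrix | None,
    tags: TagPresenceMatrix | None,
    sheet: SampleSheet,
    params: ScreenParams | None = None,
    cfg: PermutationConfig | None = None,
) -> EmpiricalNull:
    """Build the shared-permutation null for all six screens."""
    params = params or ScreenParams()
    cfg = cfg or PermutationConfig()
    ref = gm if gm is not None else tags
    male = sheet.male_mask(ref.samples).astype(np.float32)
    if not 0 < male.sum() < male.size:
        raise ValueError("both sexes must be present")
    if cfg.n_permutations * (1.0 - cfg.percentile / 100.0) < 1.0:
        logger.warning(
            "%d permutations cannot resolve the %.6g-th percentile; exact-rank rule will be used",
            cfg.n_permutations,
            cfg.percentile,
        )
    observed = {k: int(v[0]) for k, v in screen_counts_batch(gm, tags, male, params).items()}
    masks = _permutation_masks(male.astype(bool), cfg.n_permutations, cfg.seed)
    null_counts = {k: np.asarray(v) for k, v in screen_counts_batch(gm, tags, masks, params).items()}
    return EmpiricalNull(null_counts, observed, cfg.percentile, cfg.n_permutations)


@dataclass
class ValidationDecision:
    approach: str
    orientation: str
    observed: int
    threshold: float
    passed: bool


def validate(null: EmpiricalNull, cfg: PermutationConfig | None = None) -> dict[tuple[str, str], ValidationDecision]:
    """PASS iff the observed count strictly exceeds the percentile
    threshold (ties FAIL: conservative reading of 'probability < 0.01')."""
    out = {}
    for key in null.counts:
        thr = null.threshold(key)
        obs = null.observed[key]
        out[key] = ValidationDecision(key[0], key[1], obs, thr, obs > thr)
    return out


def decisions_frame(decisions: dict[tuple[str, str], ValidationDecision]) -> pd.DataFrame:
    return pd.DataFrame([vars(d) for d in decisions.values()])


# ---------------------------------------------------------------------------
# subsampling diagnostics
# ---------------------------------------------------------------------------


def _select_design_samples(
    sheet: SampleSheet,
    design: SamplingDesign,
    truth: TruthLabels | None,
) -> list[str]:
    males = [s for s, x in zip(sheet.sample_id, sheet.sex) if x == "M"]
    females = [s for s, x in zip(sheet.sample_id, sheet.sex) if x == "F"]
    if design.n_males > len(males) or design.n_females > len(females):
        raise ValueError(
            f"design {design.name} needs {design.n_males} M / {design.n_females} F, "
            f"only {len(males)} M / {len(females)} F available"
        )
    if design.males_per_haplotype is not None:
        if truth is None:
            raise ValueError("haplotype-structured design needs truth labels")
        hap_of = dict(zip(sheet.sample_id, truth.sample_haplotype))
        chosen: list[str] = []
        for h, k in enumerate(design.males_per_haplotype):
            pool = [s for s in males if hap_of.get(s, -1) == h]
            if len(pool) < k:
                raise ValueError(f"design {design.name}: only {len(pool)} males of haplotype {h}, need {k}")
            chosen.extend(pool[:k])
    else:
        chosen = males[: design.n_males]
    return chosen + females[: design.n_females]


def subsample_experiment(
    gm: GenotypeMatrix,
    tags: TagPresenceMatrix,
    sheet: SampleSheet,
    designs: list[SamplingDesign],
    params: ScreenParams | None = None,
    cfg: PermutationConfig | None = None,
    truth: TruthLabels | None = None,
) -> pd.DataFrame:
    """One validated screening run per sampling design.

    Samples are taken in their stored order within each sex (and
    within each Y haplotype for haplotype-structured designs), so the
    experiment is deterministic given the input matrices.
    """
    cfg = cfg or PermutationConfig()
    rows = []
    for d_idx, design in enumerate(designs):
        keep = _select_design_samples(sheet, design, truth)
        sub_gm = gm.subset_samples(keep)
        sub_tags = tags.subset_samples(keep)
        sub_sheet = SampleSheet(np.array(keep, dtype=object), sheet.sex_of(keep))
        sub_cfg = PermutationConfig(cfg.n_permutations, cfg.percentile, cfg.seed + d_idx)
        null = build_null(sub_gm, sub_tags, sub_sheet, params, sub_cfg)
        for key, dec in validate(null, sub_cfg).items():
            rows.append(
                {
                    "design": design.name,
                    "n_males": design.n_males,
                    "n_females": design.n_females,
                    "approach": key[0],
                    "orientation": key[1],
                    "observed": dec.observed,
                    "threshold": dec.threshold,
                    "passed": dec.passed,
                }
            )
    return pd.DataFrame(rows)
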