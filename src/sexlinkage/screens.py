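"""The three sex-linkage screens, in XY and ZW orientation.

Approach ``freq`` looks for loci with a Y-specific SNP via allele
frequencies: the X allele (the major allele in the homogametic sex)
must be at frequency >= 0.95 in the homogametic sex and inside
[0.4, 0.6] in the heterogametic sex, the pattern expected when every
heterogametic individual carries one X and one Y allele.

Approach ``het`` uses heterozygosity directly: a locus qualifies when
it is homozygous in every homogametic individual and heterozygous in
at least half of the heterogametic individuals.  It targets the same
loci as ``freq`` but is stricter in small or structured samples.

Approach ``sex_limited`` works on RADtag presence/absence: a tag
qualifies when completely absent from the homogametic sex and present
in at least half of the heterogametic sex.

All fractions are computed over non-missing calls.  Under ZW
orientation the sex roles are swapped (females heterogametic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sexlinkage.genotype_io import MISSING, GenotypeMatrix, SampleSheet, TagPresenceMatrix

APPROACHES = ("freq", "het", "sex_limited")
ORIENTATIONS = ("XY", "ZW")


@dataclass
class ScreenParams:
    x_freq_min_homogametic: float = 0.95
    x_freq_band_heterogametic: tuple[float, float] = (0.4, 0.6)
    min_het_fraction_heterogametic: float = 0.5
    min_presence_fraction_heterogametic: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.x_freq_band_heterogametic
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("x_freq_band_heterogametic must satisfy 0 <= low <= high <= 1")
        for name in ("x_freq_min_homogametic", "min_het_fraction_heterogametic", "min_presence_fraction_heterogametic"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class MarkerSet:
    """Loci flagged by one screen under one orientation."""

    approach: str
    orientation: str
    ids: np.ndarray
    stats: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_unevaluable: int = 0

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        if self.approach not in APPROACHES:
            raise ValueError(f"unknown approach {self.approach!r}")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate marker ids")

    def __len__(self) -> int:
        return len(self.ids)

    def id_set(self) -> set[str]:
        return set(self.ids)

    def to_frame(self) -> pd.DataFrame:
        df = self.stats.copy() if len(self.stats) else pd.DataFrame({"marker_id": self.ids})
        df.insert(1, "approach", self.approach)
        df.insert(2, "orientation", self.orientation)
        return df


# ---------------------------------------------------------------------------
# vectorised kernels
#
# The same arithmetic serves single datasets and batches of permuted
# sex labelings: the sex assignment enters only through matrix
# products of per-locus indicator matrices with a (samples x batch)
# 0/1 male-mask matrix, so a 1000-permutation null costs a handful of
# matrix multiplies.
# ---------------------------------------------------------------------------


def _snp_screen_flags(
    calls: np.ndarray,
    male_masks: np.ndarray,
    params: ScreenParams,
) -> dict[tuple[str, str], np.ndarray]:
    """Flag matrices (loci x batch) for the two SNP screens x two
    orientations, given a batch of male-mask columns."""
    M = np.asarray(male_masks, dtype=np.float32)
    if M.ndim == 1:
        M = M[:, None]
    F = 1.0 - M
    nonmiss = (calls != MISSING).astype(np.float32)
    dosage = np.where(calls == MISSING, 0, calls).astype(np.float32)
    het = (calls == 1).astype(np.float32)

    nm_m, nm_f = nonmiss @ M, nonmiss @ F
    a1_m, a1_f = dosage @ M, dosage @ F
    het_m, het_f = het @ M, het @ F

    out: dict[tuple[str, str], np.ndarray] = {}
    lo, hi = params.x_freq_band_heterogametic
    for orientation in ORIENTATIONS:
        if orientation == "XY":
            nm_hom, nm_het_ = nm_f, nm_m
            a1_hom, a1_het_ = a1_f, a1_m
            het_hom, het_het_ = het_f, het_m
        else:
            nm_hom, nm_het_ = nm_m, nm_f
            a1_hom, a1_het_ = a1_m, a1_f
            het_hom, het_het_ = het_m, het_f
        evaluable = (nm_hom > 0) & (nm_het_ > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f1_hom = a1_hom / (2.0 * np.maximum(nm_hom, 1e-12))
            f1_het = a1_het_ / (2.0 * np.maximum(nm_het_, 1e-12))
            # X allele = major allele in the homogametic sex; exact ties
            # break toward the reference allele (allele 0)
            x_is_alt = f1_hom > 0.5
            fx_hom = np.where(x_is_alt, f1_hom, 1.0 - f1_hom)
            fx_het = np.where(x_is_alt, f1_het, 1.0 - f1_het)
            freq_flags = evaluable & (fx_hom >= params.x_freq_min_homogametic) & (fx_het >= lo) & (fx_het <= hi)
            het_frac = het_het_ / np.maximum(nm_het_, 1e-12)
            het_flags = evaluable & (het_hom == 0) & (het_frac >= params.min_het_fraction_heterogametic)
        out[("freq", orientation)] = freq_flags
        out[("het", orientation)] = het_flags
        out[("_evaluable", orientation)] = evaluable
        if M.shape[1] == 1:
            out[("_stats", orientation)] = {
                "fx_hom": fx_hom[:, 0],
                "fx_het": fx_het[:, 0],
                "het_hom": het_hom[:, 0],
                "het_frac_het": het_frac[:, 0],
            }
    return out


def _tag_screen_flags(
    present: np.ndarray,
    male_masks: np.ndarray,
    params: ScreenParams,
) -> dict[str, np.ndarray]:
    M = np.asarray(male_masks, dtype=np.float32)
    if M.ndim == 1:
        M = M[:, None]
    F = 1.0 - M
    P = np.asarray(present, dtype=np.float32)
    pm, pf = P @ M, P @ F
    n_m, n_f = M.sum(axis=0), F.sum(axis=0)
    out = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        out["XY"] = (pf == 0) & (pm / np.maximum(n_m, 1e-12) >= params.min_presence_fraction_heterogametic)
        out["ZW"] = (pm == 0) & (pf / np.maximum(n_f, 1e-12) >= params.min_presence_fraction_heterogametic)
    return out


def screen_counts_batch(
    gm: GenotypeMatrix | None,
    tags: TagPresenceMatrix | None,
    male_masks: np.ndarray,
    params: ScreenParams | None = None,
) -> dict[tuple[str, str], np.ndarray]:
    """Marker counts per screen for a batch of male-mask columns.

    Used by the permutation machinery; guaranteed consistent with the
    single-dataset screen functions, which share these kernels.
    """
    params = params or ScreenParams()
    counts: dict[tuple[str, str], np.ndarray] = {}
    if gm is not None:
        flags = _snp_screen_flags(gm.calls, male_masks, params)
        for approach in ("freq", "het"):
            for orientation in ORIENTATIONS:
                counts[(approach, orientation)] = flags[(approach, orientation)].sum(axis=0).astype(int)
    if tags is not None:
        tflags = _tag_screen_flags(tags.present, male_masks, params)
        for orientation in ORIENTATIONS:
            counts[("sex_limited", orientation)] = tflags[orientation].sum(axis=0).astype(int)
    return counts


# ---------------------------------------------------------------------------
# public screen operations
# ---------------------------------------------------------------------------


def _check_sexes(male: np.ndarray) -> None:
    if not male.any() or male.all():
        raise ValueError("screens require at least one sample of each sex")


def screen_allele_freq(
    gm: GenotypeMatrix,
    sheet: SampleSheet,
    orientation: str = "XY",
    params: ScreenParams | None = None,
) -> MarkerSet:
    """Allele-frequency screen for loci with a Y- (or W-) specific SNP."""
    params = params or ScreenParams()
    male = sheet.male_mask(gm.samples)
    _check_sexes(male)
    flags = _snp_screen_flags(gm.calls, male, params)
    hit = flags[("freq", orientation)][:, 0]
    st = flags[("_stats", orientation)]
    stats = pd.DataFrame(
        {
            "marker_id": gm.loci[hit],
            "x_freq_homogametic": st["fx_hom"][hit],
            "x_freq_heterogametic": st["fx_het"][hit],
        }
    )
    n_uneval = int((~flags[("_evaluable", orientation)][:, 0]).sum())
    return MarkerSet("freq", orientation, gm.loci[hit], stats, n_unevaluable=n_uneval)


def screen_heterozygosity(
    gm: GenotypeMatrix,
    sheet: SampleSheet,
    orientation: str = "XY",
    params: ScreenParams | None = None,
) -> MarkerSet:
    """Heterozygosity screen: homozygous in every homogametic
    individual, heterozygous in at least half of the heterogametic."""
    params = params or ScreenParams()
    male = sheet.male_mask(gm.samples)
    _check_sexes(male)
    flags = _snp_screen_flags(gm.calls, male, params)
    hit = flags[("het", orientation)][:, 0]
    st = flags[("_stats", orientation)]
    stats = pd.DataFrame(
        {
            "marker_id": gm.loci[hit],
            "het_count_homogametic": st["het_hom"][hit].astype(int),
            "het_fraction_heterogametic": st["het_frac_het"][hit],
        }
    )
    n_uneval = int((~flags[("_evaluable", orientation)][:, 0]).sum())
    return MarkerSet("het", orientation, gm.loci[hit], stats, n_unevaluable=n_uneval)


def screen_sex_limited(
    tags: TagPresenceMatrix,
    sheet: SampleSheet,
    orientation: str = "XY",
    params: ScreenParams | None = None,
) -> MarkerSet:
    """Sex-limited-tag screen: absent from the homogametic sex, present
    in at least half of the heterogametic sex."""
    params = params or ScreenParams()
    male = sheet.male_mask(tags.samples)
    _check_sexes(male)
    flags = _tag_screen_flags(tags.present, male, params)
    hit = flags[orientation][:, 0]
    het_n = int(male.sum()) if orientation == "XY" else int((~male).sum())
    pres = tags.present[:, male if orientation == "XY" else ~male].sum(axis=1)
    stats = pd.DataFrame(
        {
            "marker_id": tags.tags[hit],
            "presence_fraction_heterogametic": pres[hit] / max(het_n, 1),
        }
    )
    return MarkerSet("sex_limited", orientation, tags.tags[hit], stats)


@dataclass
class ScreenReport:
    """All six marker sets (three approaches x two orientations) plus
    the overlap between the two SNP screens per orientation."""

    marker_sets: dict[tuple[str, str], MarkerSet]

    def counts(self) -> dict[tuple[str, str], int]:
        return {k: len(v) for k, v in self.marker_sets.items()}

    def overlap_freq_het(self, orientation: str) -> int:
        return len(self.marker_sets[("freq", orientation)].id_set() & self.marker_sets[("het", orientation)].id_set())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"approach": a, "orientation": o, "n_markers": len(ms), "n_unevaluable": ms.n_unevaluable}
            for (a, o), ms in self.marker_sets.items()
        ]
        return pd.DataFrame(rows)


def run_all_screens(
    gm: GenotypeMatrix,
    tags: TagPresenceMatrix,
    sheet: SampleSheet,
    params: ScreenParams | None = None,
) -> ScreenReport:
    params = params or ScreenParams()
    sets: dict[tuple[str, str], MarkerSet] = {}
    for orientation in ORIENTATIONS:
        sets[("freq", orientation)] = screen_allele_freq(gm, sheet, orientation, params)
        sets[("het", orientation)] = screen_heterozygosity(gm, sheet, orientation, params)
        sets[("sex_limited", orientation)] = screen_sex_limited(tags, sheet, orientation, params)
    return ScreenReport(sets)
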