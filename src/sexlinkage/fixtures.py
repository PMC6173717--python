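"""Packaged reference data: the Ranidae turnover survey and gene counts.

``load_ranidae_turnovers`` returns the curated sex-chromosome turnover
history across 28 true-frog (Ranidae) species: 8 interspecific
chromosome-change events from ancestral-state reconstruction, 3
intraspecific events (R. japonica, R. pipiens, P. porosus) and 2
homologous XY-to-ZW events (G. rugosa), together with the per-species
chromosome states and a tip probability matrix over the five
chromosomes observed as sex-linked (Chr01, Chr02, Chr03, Chr05,
Chr08).

``load_gene_counts`` returns a per-chromosome gene-count table for a
13-chromosome frog karyotype.  It is a synthetic stand-in, sized
roughly proportional to chromosome rank (~23k genes genome-wide), and
is labelled as such: use real annotation counts for real analyses.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from sexlinkage.phylo import TipStateMatrix, TurnoverEvent, TurnoverHistory

_DATA = resources.files("sexlinkage") / "data"


def _read_checked(name: str) -> str:
    meta = json.loads((_DATA / "ranidae_fixture.json").read_text())
    text = (_DATA / name).read_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    expected = meta["checksums"][name]
    if digest != expected:
        raise ValueError(f"fixture checksum mismatch for {name}: {digest} != {expected}")
    return text


def _read_tsv(name: str) -> pd.DataFrame:
    from io import StringIO

    text = _read_checked(name)
    df = pd.read_csv(StringIO(text), sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    return df


@dataclass
class RanidaeFixture:
    history: TurnoverHistory
    species: pd.DataFrame
    tip_states: TipStateMatrix
    metadata: dict

    def species_usage_counts(self) -> dict[str, int]:
        """Number of species using each chromosome for sex
        determination (a species with two described systems counts for
        both chromosomes)."""
        counts: dict[str, int] = {}
        for entry in self.species["chromosomes"]:
            if entry == "unknown":
                continue
            for chrom in str(entry).split(","):
                counts[chrom] = counts.get(chrom, 0) + 1
        return dict(sorted(counts.items()))


def load_ranidae_turnovers() -> RanidaeFixture:
    """Load the curated 28-species Ranidae turnover fixture."""
    meta = json.loads((_DATA / "ranidae_fixture.json").read_text())
    events_df = _read_tsv("ranidae_turnover_events.tsv")
    species = _read_tsv("ranidae_species_states.tsv")
    if len(species) != meta["n_species"]:
        raise ValueError("species table does not match fixture metadata")
    events = [
        TurnoverEvent(
            branch=r.branch,
            ancestral_state=r.ancestral_state,
            derived_state=r.derived_state,
            ancestral_system=r.ancestral_system,
            derived_system=r.derived_system,
            scope=r.scope,
        )
        for r in events_df.itertuples()
    ]
    states = tuple(meta["states"])
    tip_probs = {}
    for r in species.itertuples():
        if r.chromosomes == "unknown":
            tip_probs[r.species] = None
        else:
            tip_probs[r.species] = [c for c in str(r.chromosomes).split(",")]
    tips = TipStateMatrix.from_states(tip_probs, states)
    return RanidaeFixture(TurnoverHistory(events), species, tips, meta)


def load_gene_counts() -> dict[str, int]:
    """Synthetic per-chromosome gene counts for a 13-chromosome frog
    karyotype (see module docstring)."""
    df = _read_tsv("gene_counts_synthetic.tsv")
    return dict(zip(df["chromosome"], df["n_genes"].astype(int)))
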