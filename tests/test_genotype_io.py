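"""Round-trips, format semantics, locus filters and alignment-hit filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sexlinkage import genotype_io as gio
from sexlinkage import simulate
from sexlinkage.genotype_io import MISSING


def _small_matrix(seed=0, n_loci=50, n_m=6, n_f=6, **kw):
    p = simulate.PopSimParams(n_males=n_m, n_females=n_f, n_loci=n_loci, seed=seed, **kw)
    gm, tags, truth = simulate.simulate_population(p)
    return gm, tags, truth, simulate.sample_sheet_for(gm)


class TestRoundTrips:
    def test_tsv_genotypes(self, tmp_path):
        gm, *_ = _small_matrix(missing_rate=0.1)
        path = tmp_path / "g.tsv"
        gio.write_genotypes_tsv(gm, path)
        back = gio.read_genotypes(path, "tsv")
        assert list(back.loci) == list(gm.loci)
        assert list(back.samples) == list(gm.samples)
        assert (back.calls == gm.calls).all()

    def test_vcf_genotypes(self, tmp_path):
        gm, *_ = _small_matrix(missing_rate=0.2, seed=3)
        path = tmp_path / "g.vcf"
        gio.write_vcf(gm, path)
        back = gio.read_genotypes(path, "vcf")
        assert (back.calls == gm.calls).all()
        # a ./. record must come back as missing
        assert (gm.calls == MISSING).any()

    def test_vcf_multiallelic_dropped(self, tmp_path):
        path = tmp_path / "m.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=rad>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
            "rad\t1\tL1\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\n"
            "rad\t2\tL2\tA\tT,G\t.\tPASS\t.\tGT\t0/0\t1/2\n"
        )
        gm = gio.read_vcf(path)
        assert list(gm.loci) == ["L1"]

    def test_tags_and_sheet(self, tmp_path):
        _, tags, _, sheet = _small_matrix(prop_sexlinked=0.2, prop_sex_limited=1.0, prop_y_snp=0.0, prop_x_hemizygous=0.0)
        gio.write_tag_presence(tags, tmp_path / "t.tsv")
        back = gio.read_tag_presence(tmp_path / "t.tsv")
        assert (back.present == tags.present).all()
        gio.write_sample_sheet(sheet, tmp_path / "s.tsv")
        sback = gio.read_sample_sheet(tmp_path / "s.tsv")
        assert list(sback.sample_id) == list(sheet.sample_id)
        assert list(sback.sex) == list(sheet.sex)

    def test_gzip_tolerated(self, tmp_path):
        gm, *_ = _small_matrix()
        path = tmp_path / "g.tsv.gz"
        gio.write_genotypes_tsv(gm, path)
        assert (gio.read_genotypes_tsv(path).calls == gm.calls).all()

    def test_sample_absent_from_sheet_named(self):
        gm, _, _, sheet = _small_matrix()
        bad = gio.SampleSheet(sheet.sample_id[:-1], sheet.sex[:-1])
        with pytest.raises(KeyError, match=str(gm.samples[-1])):
            gio.check_samples_in_sheet(gm, bad)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            gio.GenotypeMatrix(["a", "a"], ["s1"], [[0], [1]])
        with pytest.raises(ValueError):
            gio.SampleSheet(["s1", "s1"], ["M", "F"])
        with pytest.raises(ValueError):
            gio.SampleSheet(["s1"], ["X"])


class TestLocusFilter:
    def _matrix_from_rows(self, rows, sexes):
        rows = np.asarray(rows, dtype=np.int8)
        loci = [f"L{i}" for i in range(rows.shape[0])]
        samples = [f"S{i}" for i in range(rows.shape[1])]
        gm = gio.GenotypeMatrix(loci, samples, rows)
        sheet = gio.SampleSheet(samples, sexes)
        return gm, sheet

    def test_presence_threshold_is_per_sex(self):
        # 100 males, 74 genotyped -> below the 75% floor despite all
        # females being genotyped
        male_row = [0] * 74 + [MISSING] * 26
        female_row = [0] * 30
        gm, sheet = self._matrix_from_rows([male_row + female_row], ["M"] * 100 + ["F"] * 30)
        out = gio.filter_loci(gm, sheet, gio.FilterParams(min_maf=0.0))
        assert out.n_loci == 0

    def test_all_het_locus_removed(self):
        gm, sheet = self._matrix_from_rows([[1] * 8], ["M"] * 4 + ["F"] * 4)
        assert gio.filter_loci(gm, sheet).n_loci == 0

    def test_boundary_values_inclusive(self):
        # presence exactly 0.75 in both sexes, maf exactly 0.05 -> retained
        calls = np.zeros((1, 40), dtype=np.int8)
        calls[0, :5] = MISSING
        calls[0, 20:25] = MISSING
        nonmiss = 30
        # 3 alt alleles of 60 -> maf 0.05
        calls[0, 5:8] = 1
        gm, sheet = self._matrix_from_rows(calls, ["M"] * 20 + ["F"] * 20)
        out = gio.filter_loci(gm, sheet, gio.FilterParams())
        assert out.n_loci == 1

    def test_matches_independent_per_locus_oracle(self):
        gm, _, _, sheet = _small_matrix(seed=9, n_loci=400, n_m=15, n_f=15, missing_rate=0.15, error_rate=0.01)
        params = gio.FilterParams()
        out = gio.filter_loci(gm, sheet, params)
        male = sheet.male_mask(gm.samples)
        keep = []
        for row in gm.calls:  # plain per-locus recomputation
            m, f = row[male], row[~male]
            pm = (m != MISSING).mean()
            pf = (f != MISSING).mean()
            obs = row[row != MISSING]
            if len(obs) == 0:
                keep.append(False)
                continue
            p_alt = obs.sum() / (2 * len(obs))
            maf = min(p_alt, 1 - p_alt)
            het = (obs == 1).mean()
            keep.append(pm >= 0.75 and pf >= 0.75 and maf >= 0.05 and het <= 0.75)
        assert set(out.loci) == set(gm.loci[np.array(keep)])

    @settings(max_examples=15, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_idempotent(self, seed):
        gm, _, _, sheet = _small_matrix(seed=seed, n_loci=120, missing_rate=0.2)
        once = gio.filter_loci(gm, sheet)
        twice = gio.filter_loci(once, sheet)
        assert list(once.loci) == list(twice.loci)

    def test_heterogametic_majority_can_lose_sexlinked_loci(self):
        """With males >75% of samples, a fully sex-linked locus (het in
        every male) exceeds the heterozygosity ceiling and is removed."""
        n_m, n_f = 16, 4  # males are 80% of samples
        row = [1] * n_m + [0] * n_f
        gm, sheet = self._matrix_from_rows([row], ["M"] * n_m + ["F"] * n_f)
        assert gio.filter_loci(gm, sheet).n_loci == 0
        # same locus survives with balanced sexes
        row2 = [1] * 8 + [0] * 12
        gm2, sheet2 = self._matrix_from_rows([row2], ["M"] * 8 + ["F"] * 12)
        assert gio.filter_loci(gm2, sheet2).n_loci == 1

    def test_filter_order_invariance(self):
        """Applying the three rules in any order leaves the same set,
        since each statistic ignores the other rules' outcomes."""
        gm, _, _, sheet = _small_matrix(seed=21, n_loci=300, missing_rate=0.2, error_rate=0.02)
        stats = gio.locus_filter_stats(gm, sheet)
        p = gio.FilterParams()
        rules = {
            "presence": (stats["presence_m"] >= p.min_presence_per_sex) & (stats["presence_f"] >= p.min_presence_per_sex),
            "maf": stats["maf"].fillna(-1) >= p.min_maf,
            "het": stats["obs_het"].fillna(2) <= p.max_obs_het,
        }
        import itertools

        sets = []
        for order in itertools.permutations(rules):
            keep = np.ones(gm.n_loci, dtype=bool)
            for r in order:
                keep &= rules[r].to_numpy()
            sets.append(frozenset(gm.loci[keep]))
        assert len(set(sets)) == 1
        assert sets[0] == frozenset(gio.filter_loci(gm, sheet, p).loci)


class TestAlignmentFilter:
    def _hits(self, rows):
        return pd.DataFrame(
            [(q, s, 100.0, 92, 0, 0, 1, 92, 1, 92, e, b) for q, s, e, b in rows],
            columns=gio.BLAST6_COLUMNS,
        )

    def test_single_strong_hit_retained(self):
        out = gio.filter_alignment_hits(self._hits([("q1", "s1", 1e-25, 100)]))
        assert list(out["query_id"]) == ["q1"]

    def test_next_hit_ratio_rule(self):
        keep = self._hits([("q1", "s1", 1e-30, 100), ("q1", "s2", 1e-24, 90)])
        drop = self._hits([("q2", "s1", 1e-30, 100), ("q2", "s2", 1e-28, 90)])
        assert len(gio.filter_alignment_hits(keep)) == 1
        assert len(gio.filter_alignment_hits(drop)) == 0

    def test_evalue_ceiling_strict(self):
        assert len(gio.filter_alignment_hits(self._hits([("q1", "s1", 1e-19, 100)]))) == 0
        assert len(gio.filter_alignment_hits(self._hits([("q1", "s1", 1e-20, 100)]))) == 0  # not strictly below

    def test_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("q1\ts1\t100.0\t92\t0\t0\t1\t92\t1\t92\t1e-30\t100\nbad line\n")
        with pytest.raises(ValueError, match="line 2"):
            gio.read_alignment_hits(path)

    def test_roundtrip(self, tmp_path):
        hits = self._hits([("q1", "s1", 1e-30, 100), ("q2", "s2", 1e-25, 90)])
        gio.write_alignment_hits(hits, tmp_path / "h.tsv")
        back = gio.read_alignment_hits(tmp_path / "h.tsv")
        assert (back["query_id"] == hits["query_id"]).all()
        assert back["evalue"].tolist() == hits["evalue"].tolist()
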