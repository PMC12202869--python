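"""Hit parsing, best-hit splitting, coverage, completeness, diversity."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ventlight import metagenome as mg


def _hit(read, gene, bits=100.0, s=1, e=50):
    return mg.HitRecord(read_id=read, gene_id=gene, percent_identity=90.0,
                        align_length=abs(e - s) + 1, bitscore=bits,
                        subject_start=s, subject_end=e)


@pytest.fixture(scope="module")
def catalog():
    return mg.load_default_catalog()


class TestCatalog:
    def test_packaged_catalog_covers_every_category(self, catalog):
        for cat in mg.APPARATUS_CATEGORIES:
            assert catalog.genes_in(cat), cat

    def test_farlip_probes_present(self, catalog):
        symbols = {catalog.symbol(g) for g in catalog.gene_ids}
        assert set(mg.FARLIP_PROBES) <= symbols

    def test_duplicate_gene_id_rejected(self, tmp_path):
        p = tmp_path / "cat.tsv"
        p.write_text("gene_id\tsymbol\tcategory\tlength_aa\n"
                     "K1\tpsaA\tPSI\t700\nK1\tpsaB\tPSI\t700\n")
        with pytest.raises(ValueError, match="duplicate"):
            mg.GeneCatalog.from_tsv(p)


class TestParseHits:
    def _write(self, tmp_path, rows):
        p = tmp_path / "hits.tsv"
        p.write_text("".join("\t".join(map(str, r)) + "\n" for r in rows))
        return p

    def test_well_formed_rows(self, tmp_path):
        rows = [("r1", "K02689", 95.0, 60, 0, 0, 1, 180, 1, 60, "1e-30", 120.0),
                ("r2", "K02690", 90.0, 60, 2, 0, 1, 180, 31, 90, "1e-25", 110.0),
                ("r3", "K02689", 85.0, 50, 5, 1, 1, 150, 100, 149, "1e-20", 95.0)]
        records = mg.parse_hits(self._write(tmp_path, rows))
        assert len(records) == 3
        assert records[0].gene_id == "K02689"

    def test_minus_frame_coordinates_normalized(self, tmp_path):
        rows = [("r1", "K02689", 95.0, 60, 0, 0, 180, 1, 90, 31, "1e-30", 120.0)]
        rec = mg.parse_hits(self._write(tmp_path, rows))[0]
        assert (rec.subject_start, rec.subject_end) == (31, 90)

    def test_empty_file(self, tmp_path):
        assert mg.parse_hits(self._write(tmp_path, [])) == []

    def test_malformed_row_names_line(self, tmp_path):
        rows = [("r1", "K02689", 95.0, 60, 0, 0, 1, 180, 1, 60, "1e-30", 120.0),
                ("r2", "K02690", "short")]
        with pytest.raises(ValueError, match=":2:"):
            mg.parse_hits(self._write(tmp_path, rows))


class TestBestHits:
    def test_keeps_highest_bitscore(self):
        best = mg.best_hits([_hit("r1", "A", 50.0), _hit("r1", "B", 80.0)])
        assert [r.gene_id for r in best["r1"]] == ["B"]

    def test_ties_retained_as_shared_set(self):
        best = mg.best_hits([_hit("r1", "A", 80.0), _hit("r1", "B", 80.0)])
        assert {r.gene_id for r in best["r1"]} == {"A", "B"}

    def test_empty_input(self):
        assert mg.best_hits([]) == {}


class TestAggregateReadHits:
    def test_shared_read_split_in_half(self):
        best = mg.best_hits([_hit("r1", "A", 80.0), _hit("r1", "B", 80.0)])
        counts = mg.aggregate_read_hits(best)
        assert counts == {"A": 0.5, "B": 0.5}

    def test_unique_reads_count_fully(self):
        best = mg.best_hits([_hit(f"r{i}", "A") for i in range(10)])
        assert mg.aggregate_read_hits(best) == {"A": 10.0}

    @given(st.lists(
        st.tuples(st.integers(0, 30), st.lists(st.sampled_from("ABCDE"),
                                               min_size=1, max_size=4,
                                               unique=True)),
        min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_count_conservation_under_splitting(self, reads):
        # every mapped read contributes exactly 1 in total, however shared
        records = []
        for ridx, genes in reads:
            for g in genes:
                records.append(_hit(f"r{ridx}", g, bits=77.0))
        best = mg.best_hits(records)
        counts = mg.aggregate_read_hits(best)
        assert sum(counts.values()) == pytest.approx(len(best), rel=1e-12)


def _coverage_oracle(records, length):
    """Brute-force per-position boolean coverage."""
    covered = np.zeros(length, dtype=bool)
    for r in records:
        covered[r.subject_start - 1:min(r.subject_end, length)] = True
    return covered.mean()


class TestCoveredFraction:
    def test_overlapping_intervals_cover_fully(self):
        recs = [_hit("r1", "A", s=1, e=50), _hit("r2", "A", s=41, e=100)]
        assert mg.covered_fraction(recs, 100) == 1.0

    def test_partial_interval(self):
        assert mg.covered_fraction([_hit("r1", "A", s=1, e=40)], 100) == 0.4

    def test_no_hits(self):
        assert mg.covered_fraction([], 100) == 0.0

    def test_matches_positional_oracle_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            length = int(rng.integers(20, 1000))
            recs = []
            for i in range(rng.integers(0, 25)):
                s = int(rng.integers(1, length + 1))
                e = int(min(length, s + rng.integers(0, 120)))
                recs.append(_hit(f"r{i}", "A", s=s, e=e))
            assert mg.covered_fraction(recs, length) == pytest.approx(
                _coverage_oracle(recs, length), abs=1e-12)


class TestPresenceAndCompleteness:
    def _coverage_frame(self, rows):
        return pd.DataFrame(rows, columns=["dataset", "gene_id",
                                           "read_hits", "normalized_hits",
                                           "covered_fraction"])

    @pytest.mark.parametrize("cov,present", [(0.85, True), (0.79, False),
                                             (0.80, True)])
    def test_threshold_convention(self, cov, present):
        df = self._coverage_frame([("d1", "g1", 1.0, 1.0, cov)])
        assert bool(mg.gene_presence(df).loc["d1", "g1"]) is present

    def test_eight_of_ten_gives_point_eight(self, catalog):
        genes = sorted(catalog.genes_in("PSII"))[:10]
        sub = mg.GeneCatalog({g: ("psb", "PSII", 100) for g in genes})
        rows = [("d1", g, 1.0, 1.0, 1.0 if i < 8 else 0.3)
                for i, g in enumerate(genes)]
        presence = mg.gene_presence(self._coverage_frame(rows))
        matrix = mg.apparatus_completeness(presence, sub, categories=("PSII",))
        assert matrix.values.loc["d1", "PSII"] == pytest.approx(0.8)

    def test_all_present_and_none_present(self, catalog):
        cats = tuple(c for c in mg.APPARATUS_CATEGORIES if c != "FaRLiP")
        rows_full, rows_zero = [], []
        for g in catalog.gene_ids:
            rows_full.append(("d1", g, 1.0, 1.0, 1.0))
            rows_zero.append(("d1", g, 0.0, 0.0, 0.0))
        for rows, expected in ((rows_full, 1.0), (rows_zero, 0.0)):
            presence = mg.gene_presence(self._coverage_frame(rows))
            matrix = mg.apparatus_completeness(presence, catalog,
                                               categories=cats)
            assert (matrix.values.loc["d1"] == expected).all()

    def test_monotone_in_added_hits(self, catalog):
        cats = ("PSI", "PSII")
        genes = catalog.gene_ids
        rng = np.random.default_rng(0)
        cov1 = {g: float(rng.uniform(0, 1)) for g in genes}
        cov2 = {g: min(1.0, cov1[g] + float(rng.uniform(0, 0.5))) for g in genes}
        f1 = self._coverage_frame([("d", g, 1, 1, c) for g, c in cov1.items()])
        f2 = self._coverage_frame([("d", g, 1, 1, c) for g, c in cov2.items()])
        m1 = mg.apparatus_completeness(mg.gene_presence(f1), catalog,
                                       categories=cats)
        m2 = mg.apparatus_completeness(mg.gene_presence(f2), catalog,
                                       categories=cats)
        assert (m2.values.to_numpy() >= m1.values.to_numpy()).all()

    def test_unknown_category_rejected(self, catalog):
        df = self._coverage_frame([("d1", "K02689", 1.0, 1.0, 1.0)])
        with pytest.raises(ValueError):
            mg.apparatus_completeness(mg.gene_presence(df), catalog,
                                      categories=("PSX",))


class TestFarlip:
    def test_probe_present_flags_dataset(self, catalog):
        probe = next(g for g in catalog.gene_ids
                     if catalog.symbol(g) == "apcD2")
        presence = pd.DataFrame({probe: [True, False]}, index=["d1", "d2"])
        flags = mg.farlip_check(presence, catalog)
        assert bool(flags["d1"]) and not bool(flags["d2"])

    def test_missing_probes_raise(self):
        cat = mg.GeneCatalog({"K1": ("psaA", "PSI", 700)})
        presence = pd.DataFrame({"K1": [True]}, index=["d1"])
        with pytest.raises(ValueError, match="probe"):
            mg.farlip_check(presence, cat)


class TestCommunityProfile:
    def test_single_species_has_zero_entropy(self):
        abund, h = mg.community_profile({"syn": 12.0})
        assert abund == {"syn": 1.0}
        assert h == 0.0

    def test_uniform_four_species(self):
        _, h = mg.community_profile({c: 5.0 for c in "abcd"})
        assert h == pytest.approx(math.log(4), rel=1e-12)

    def test_abundances_sum_to_one(self):
        abund, _ = mg.community_profile({"a": 3.2, "b": 1.1, "c": 0.7})
        assert sum(abund.values()) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            mg.community_profile({"a": 0.0, "b": 0.0})


class TestMatrixIO:
    def test_round_trip(self, tmp_path):
        values = pd.DataFrame({"PSI": [0.25, 1.0], "PBS_APC": [0.5, 0.0]},
                              index=["C1_1", "N_1"])
        values.index.name = "dataset"
        matrix = mg.CompletenessMatrix(values=values,
                                       meta={"C1_1": "C1", "N_1": "N"})
        path = tmp_path / "m.tsv"
        mg.export_matrix(matrix, path)
        back = mg.read_matrix(path)
        assert back.meta == matrix.meta
        pd.testing.assert_frame_equal(
            back.values.sort_index(), matrix.values.sort_index(),
            check_exact=False, atol=5e-4)

    def test_rows_grouped_by_vent_type(self, tmp_path):
        values = pd.DataFrame({"PSI": [0.1, 0.2, 0.3]},
                              index=["N_1", "C1_1", "S_1"])
        values.index.name = "dataset"
        matrix = mg.CompletenessMatrix(
            values=values, meta={"N_1": "N", "C1_1": "C1", "S_1": "S"})
        assert list(matrix.grouped().index) == ["C1_1", "S_1", "N_1"]

    def test_empty_matrix_writes_header_only(self, tmp_path):
        values = pd.DataFrame(columns=["PSI", "PSII"])
        values.index.name = "dataset"
        matrix = mg.CompletenessMatrix(values=values, meta={})
        path = tmp_path / "empty.tsv"
        mg.export_matrix(matrix, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1

    def test_cells_written_to_three_decimals(self, tmp_path):
        values = pd.DataFrame({"PSI": [1.0 / 3.0]}, index=["C1_1"])
        values.index.name = "dataset"
        mg.export_matrix(mg.CompletenessMatrix(values, {"C1_1": "C1"}),
                         tmp_path / "m.tsv")
        assert "0.333" in (tmp_path / "m.tsv").read_text()
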