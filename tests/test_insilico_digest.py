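import itertools

import pytest
from hypothesis import given, settings, strategies as st

from bloodpmf.insilico_digest import (
    DigestParams,
    PROTEOTYPIC,
    ProteinRecord,
    SHARED,
    TheoreticalTable,
    annotate_specificity,
    cleavage_sites,
    enumerate_peptides,
    read_fasta,
    read_table,
    write_table,
)
from bloodpmf.peptide_mass import IonSpec, Peptide, mz

from conftest import (
    ALPHA_GLOBIN_CONTEXT,
    BETA_GLOBIN_CONTEXT,
    CHICKEN_GAPDH_CONTEXT,
    MAMMAL_GAPDH_CONTEXT,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_digest(sequence, params):
    """Oracle: test every substring against the cleavage-site rule."""
    n = len(sequence)

    def is_boundary(k):  # a cut is legal between k-1 and k
        return sequence[k - 1] in "KR" and sequence[k] != "P"

    out = set()
    for i in range(n):
        for j in range(i + 1, n + 1):
            if i != 0 and not is_boundary(i):
                continue
            if j != n and not is_boundary(j):
                continue
            mc = sum(1 for k in range(i + 1, j) if is_boundary(k))
            if mc > params.max_missed_cleavages:
                continue
            sub = sequence[i:j]
            mets = [p + 1 for p, c in enumerate(sub) if c == "M"]
            states = [frozenset()]
            if params.variable_met_oxidation and mets:
                if len(mets) > 4:
                    states = [frozenset(), frozenset(mets)]
                else:
                    states = [
                        frozenset(c)
                        for k in range(len(mets) + 1)
                        for c in itertools.combinations(mets, k)
                    ]
            for ox in states:
                value = mz(Peptide(sub, ox), IonSpec(1))
                if params.mz_min <= value <= params.mz_max:
                    out.add((sub, mc, ox))
    return out


class TestCleavageSites:
    def test_keil_suppression(self):
        # K followed by P: cut suppressed
        assert cleavage_sites("AKPA") == []

    def test_terminal_excluded(self):
        assert cleavage_sites("AKAR") == [2]

    def test_grakg(self):
        assert cleavage_sites("GRAKG") == [2, 4]


class TestEnumeratePeptides:
    def test_mkgr_exhaustive(self):
        rec = ProteinRecord("X", "spX", "toy", "MKGR")
        params = DigestParams(max_missed_cleavages=0, mz_min=0.001, mz_max=3000.0)
        got = {(e.peptide.sequence, e.missed_cleavages, e.peptide.oxidized_positions)
               for e in enumerate_peptides(rec, params)}
        assert got == {
            ("MK", 0, frozenset()),
            ("MK", 0, frozenset({1})),
            ("GR", 0, frozenset()),
        }

    def test_missed_cleavage_monotonicity(self):
        rec = ProteinRecord("X", "spX", "toy", "MAKRGWTKLLVVYPWTQRAK")
        params0 = DigestParams(max_missed_cleavages=0, mz_min=0.001, mz_max=5000.0)
        params2 = DigestParams(max_missed_cleavages=2, mz_min=0.001, mz_max=5000.0)
        assert len(enumerate_peptides(rec, params2)) >= len(enumerate_peptides(rec, params0))

    def test_range_filter(self):
        rec = ProteinRecord("X", "spX", "toy", CHICKEN_GAPDH_CONTEXT * 2)
        for e in enumerate_peptides(rec, DigestParams()):
            assert 600.0 <= e.mz <= 2000.0

    def test_gapdh_marker_released(self):
        for context, marker, printed in [
            (CHICKEN_GAPDH_CONTEXT, "LVSWYDNEFGYSNR", 1749.787),
            (MAMMAL_GAPDH_CONTEXT, "LISWYDNEFGYSNR", 1763.802),
        ]:
            rec = ProteinRecord("X", "spX", "gapdh", context)
            hits = [
                e for e in enumerate_peptides(rec, DigestParams())
                if e.peptide.sequence == marker and e.missed_cleavages == 0
                and not e.peptide.oxidized_positions
            ]
            assert len(hits) == 1
            assert hits[0].mz == pytest.approx(printed, abs=2e-3)

    @settings(max_examples=150, deadline=None)
    @given(
        st.text(alphabet=AA, min_size=1, max_size=30),
        st.integers(min_value=0, max_value=2),
    )
    def test_matches_brute_force_oracle(self, sequence, mc):
        params = DigestParams(max_missed_cleavages=mc, mz_min=0.001, mz_max=4000.0)
        rec = ProteinRecord("X", "spX", "toy", sequence)
        got = {(e.peptide.sequence, e.missed_cleavages, e.peptide.oxidized_positions)
               for e in enumerate_peptides(rec, params)}
        assert got == brute_force_digest(sequence, params)


class TestSpecificity:
    def _entries(self, species, context):
        rec = ProteinRecord(f"ACC_{species}", species, "globin", context)
        return enumerate_peptides(rec, DigestParams())

    def test_shared_beta_globin_peptide(self):
        per_species = {
            sp: self._entries(sp, BETA_GLOBIN_CONTEXT)
            for sp in ("human", "porcine", "bovine")
        }
        table = annotate_specificity(per_species)
        hits = [e for e in table.entries if e.peptide.sequence == "LLVVYPWTQR"]
        assert hits and all(e.specificity == SHARED for e in hits)
        assert all(e.shared_species == frozenset({"human", "porcine", "bovine"}) for e in hits)

    def test_alpha_globin_human_bovine(self):
        per_species = {
            "human": self._entries("human", ALPHA_GLOBIN_CONTEXT),
            "bovine": self._entries("bovine", ALPHA_GLOBIN_CONTEXT),
            "chicken": self._entries("chicken", CHICKEN_GAPDH_CONTEXT),
        }
        table = annotate_specificity(per_species)
        hits = [e for e in table.entries if e.peptide.sequence == "VGGHAAEYGAEALER"]
        assert hits and all(e.shared_species == frozenset({"human", "bovine"}) for e in hits)

    def test_single_species_all_proteotypic(self):
        table = annotate_specificity({"human": self._entries("human", BETA_GLOBIN_CONTEXT)})
        assert all(e.specificity == PROTEOTYPIC for e in table.entries)

    def test_specificity_monotone_in_panel(self):
        small = annotate_specificity(
            {"human": self._entries("human", BETA_GLOBIN_CONTEXT)}
        )
        large = annotate_specificity(
            {
                "human": self._entries("human", BETA_GLOBIN_CONTEXT),
                "bovine": self._entries("bovine", BETA_GLOBIN_CONTEXT),
            }
        )
        small_map = {(e.accession, e.peptide): e.shared_species for e in small.entries}
        for e in large.entries:
            key = (e.accession, e.peptide)
            if key in small_map:
                assert small_map[key] <= e.shared_species


class TestFastaIO:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "toy.fasta"
        path.write_text(
            ">sp|P00356|G3P_CHICK GAPDH OS=Gallus gallus\n"
            f"{CHICKEN_GAPDH_CONTEXT}\n"
            ">myprotein\n"
            f"{BETA_GLOBIN_CONTEXT}\n"
        )
        records = read_fasta(path)
        assert len(records) == 2
        assert records[0].accession == "P00356"
        assert records[0].species == "Gallus gallus"
        assert records[0].sequence == CHICKEN_GAPDH_CONTEXT
        assert records[1].accession == "myprotein"

    def test_species_map_overrides(self, tmp_path):
        path = tmp_path / "toy.fasta"
        path.write_text(">sp|P00356|G3P_CHICK\nMAKR\n")
        records = read_fasta(path, species_map={"P00356": "chicken"})
        assert records[0].species == "chicken"

    def test_digit_in_sequence_rejected_with_line(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">ok\nMAKR\n>bad\nMA1R\n")
        with pytest.raises(ValueError, match=r"bad\.fasta:4"):
            read_fasta(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(ValueError, match="no FASTA records"):
            read_fasta(path)


class TestTableIO:
    def _table(self):
        per_species = {
            "human": enumerate_peptides(
                ProteinRecord("A1", "human", "globin", BETA_GLOBIN_CONTEXT), DigestParams()
            ),
            "bovine": enumerate_peptides(
                ProteinRecord("A2", "bovine", "globin", BETA_GLOBIN_CONTEXT), DigestParams()
            ),
        }
        return annotate_specificity(per_species)

    def test_round_trip(self, tmp_path):
        table = self._table()
        path = tmp_path / "table.tsv"
        write_table(table, path)
        back = read_table(path)
        assert len(back) == len(table)
        for a, b in zip(table.entries, back.entries):
            assert a.accession == b.accession
            assert a.peptide == b.peptide
            assert a.mz == pytest.approx(b.mz, abs=1e-6)
            assert a.shared_species == b.shared_species

    def test_empty_table_header_only(self, tmp_path):
        table = TheoreticalTable(entries=(), params=DigestParams(), panel_species=frozenset())
        path = tmp_path / "empty.tsv"
        write_table(table, path)
        back = read_table(path)
        assert len(back) == 0

    def test_non_numeric_mz_rejected(self, tmp_path):
        table = self._table()
        path = tmp_path / "table.tsv"
        write_table(table, path)
        text = path.read_text().splitlines()
        fields = text[2].split("\t")
        fields[5] = "not-a-number"
        text[2] = "\t".join(fields)
        path.write_text("\n".join(text) + "\n")
        with pytest.raises(ValueError, match="malformed row"):
            read_table(path)

    def test_entries_sorted_by_mz(self):
        table = self._table()
        mzs = [e.mz for e in table.entries]
        assert mzs == sorted(mzs)
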