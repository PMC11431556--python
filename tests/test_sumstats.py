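"""I/O round-trips, record validation, and allele harmonization."""

import numpy as np
import pandas as pd
import pytest

from mrmediate import GwasSumStats, harmonize, read_sumstats, write_sumstats
from tests.conftest import make_sumstats


class TestReadWrite:
    def test_round_trip_is_identity(self, tmp_path):
        s = make_sumstats(BETA=[-0.0128, 0.2, 1.5e-3], SE=[0.01, 0.02, 0.03])
        path = tmp_path / "x.tsv"
        write_sumstats(s, path)
        back = read_sumstats(path, trait_id=s.trait_id)
        pd.testing.assert_frame_equal(back.data, s.data, check_dtype=False,
                                      check_exact=True)
        # sign and >=6 significant digits survive the text round-trip
        assert back.data["BETA"].iloc[0] == -0.0128

    def test_gzip_and_csv_dialects_accepted(self, tmp_path):
        s = make_sumstats(BETA=[0.1, -0.2])
        gz = tmp_path / "x.tsv.gz"
        s.data.to_csv(gz, sep="\t", index=False, compression="gzip")
        assert read_sumstats(gz).n_snp == 2
        csv = tmp_path / "x.csv"
        s.data.rename(columns={"SNP": "variant_id", "P": "p_value"}).to_csv(csv, index=False)
        assert read_sumstats(csv).n_snp == 2  # synonym headers resolved

    @pytest.mark.parametrize("bad_col,bad_val", [
        ("SE", 0.0),          # non-positive standard error
        ("EA", "AT"),         # multi-base allele
        ("EAF", 1.0),         # frequency at the boundary
        ("P", 0.0),           # p-value outside (0, 1]
    ])
    def test_invalid_rows_dropped_not_fatal(self, tmp_path, bad_col, bad_val):
        s = make_sumstats(BETA=[0.1, 0.2, 0.3])
        df = s.data.copy()
        df.loc[1, bad_col] = bad_val
        path = tmp_path / "messy.tsv"
        df.to_csv(path, sep="\t", index=False)
        back = read_sumstats(path)
        assert back.n_snp == 2
        assert "rs2" not in set(back.data["SNP"])

    def test_missing_column_is_fatal_and_named(self, tmp_path):
        path = tmp_path / "nocol.tsv"
        make_sumstats(BETA=[0.1]).data.drop(columns=["SE"]).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="SE"):
            read_sumstats(path)

    def test_empty_file_is_fatal(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises((ValueError, pd.errors.EmptyDataError)):
            read_sumstats(path)

    def test_empty_record_set_writes_header_only(self, tmp_path):
        s = GwasSumStats("empty", "continuous")
        path = tmp_path / "empty.tsv"
        write_sumstats(s, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("SNP\t")

    def test_duplicate_snp_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_sumstats(SNP=["rs1", "rs1"], BETA=[0.1, 0.2])


class TestHarmonize:
    def test_swapped_alleles_flip_outcome_beta(self):
        exp = make_sumstats("X", EA=["A"], OA=["G"], BETA=[0.2], EAF=[0.3])
        out = make_sumstats("Y", EA=["G"], OA=["A"], BETA=[0.1], EAF=[0.7])
        h = harmonize(exp, out)
        assert h.k == 1
        assert h.data["beta_y"].iloc[0] == pytest.approx(-0.1)
        assert h.data["eaf_y"].iloc[0] == pytest.approx(0.3)

    def test_strand_complement_resolved_before_comparison(self):
        # outcome reported on the other strand: A/G vs T/C
        exp = make_sumstats("X", EA=["A"], OA=["G"], BETA=[0.2])
        out = make_sumstats("Y", EA=["T"], OA=["C"], BETA=[0.1])
        h = harmonize(exp, out)
        assert h.k == 1
        assert h.data["beta_y"].iloc[0] == pytest.approx(0.1)

    def test_identical_coding_is_identity(self):
        exp = make_sumstats("X", BETA=[0.2, -0.1])
        out = make_sumstats("Y", BETA=[0.1, 0.05])
        h = harmonize(exp, out)
        np.testing.assert_allclose(h.data["beta_y"], [0.1, 0.05])

    def test_palindromic_ambiguous_dropped_by_policy(self):
        exp = make_sumstats("X", EA=["A", "A"], OA=["T", "T"], EAF=[0.50, 0.10])
        out = make_sumstats("Y", EA=["A", "A"], OA=["T", "T"], EAF=[0.50, 0.10])
        assert harmonize(exp, out, "drop_ambiguous").k == 1      # eaf 0.10 survives
        assert harmonize(exp, out, "drop_all").k == 0
        assert harmonize(exp, out, "keep").k == 2

    def test_mismatched_allele_pairs_dropped(self):
        exp = make_sumstats("X", EA=["A"], OA=["G"])
        out = make_sumstats("Y", EA=["A"], OA=["C"])
        assert harmonize(exp, out).k == 0

    def test_zero_shared_snps_warns_not_fatal(self):
        exp = make_sumstats("X", SNP=["rs1"])
        out = make_sumstats("Y", SNP=["rs2"])
        h = harmonize(exp, out)
        assert h.k == 0

    def test_idempotent_on_already_harmonized_pair(self, rng):
        exp = make_sumstats("X", BETA=list(rng.normal(0, 0.1, 10)),
                            EAF=list(rng.uniform(0.05, 0.95, 10)))
        out = make_sumstats("Y", BETA=list(rng.normal(0, 0.1, 10)),
                            EAF=list(rng.uniform(0.05, 0.95, 10)))
        h1 = harmonize(exp, out)
        # re-harmonizing the outcome restricted to h1's rows changes nothing
        out2 = GwasSumStats("Y", "continuous",
                            out.data[out.data["SNP"].isin(h1.data["SNP"])].reset_index(drop=True))
        h2 = harmonize(exp, out2)
        pd.testing.assert_frame_equal(h1.data, h2.data)

    def test_flipping_outcome_coding_gives_identical_result(self, rng):
        """Relabelling the outcome's alleles (swap EA/OA, negate beta,
        1-EAF) must yield the same harmonized set."""
        exp = make_sumstats("X", EA=["A", "C", "G"], OA=["G", "T", "A"],
                            BETA=[0.2, -0.1, 0.05], EAF=[0.2, 0.4, 0.7])
        out = make_sumstats("Y", EA=["A", "C", "G"], OA=["G", "T", "A"],
                            BETA=[0.1, 0.3, -0.2], EAF=[0.25, 0.35, 0.75])
        flipped = out.data.copy()
        flipped[["EA", "OA"]] = flipped[["OA", "EA"]].to_numpy()
        flipped["BETA"] = -flipped["BETA"]
        flipped["EAF"] = 1.0 - flipped["EAF"]
        out_flipped = GwasSumStats("Y", "continuous", flipped)
        pd.testing.assert_frame_equal(harmonize(exp, out).data,
                                      harmonize(exp, out_flipped).data)
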