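"""Summary-statistic IO, harmonization, bilateral averaging and meta-analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pathprs.errors import (
    BuildMismatchError,
    EmptyInputError,
    EmptyOverlapError,
    FormatError,
)
from pathprs.sumstats import (
    APOE_MASK,
    MHC_MASK,
    average_bilateral,
    exclude_regions,
    filter_maf,
    harmonize,
    meta_estimates,
    meta_snp,
    read_summary_stats,
    write_summary_stats,
)

from conftest import make_dataset


def _write_tsv(path, rows):
    cols = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P", "EAF", "N"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    return path


def _row(snp, bp, **kw):
    base = dict(SNP=snp, CHR="1", BP=bp, A1="A", A2="G", BETA=0.1, SE=0.05,
                P=0.5, EAF=0.3, N=1000)
    base.update(kw)
    return base


class TestRead:
    def test_well_formed_file_round_trips(self, tmp_path):
        path = _write_tsv(tmp_path / "ss.tsv", [_row(f"rs{i}", 100 * i) for i in range(1, 6)])
        ds = read_summary_stats(path)
        assert ds.n_snps == 5
        assert list(ds.df["pos"]) == sorted(ds.df["pos"])

    def test_invalid_rows_dropped_not_fatal(self, tmp_path):
        rows = [
            _row("rs1", 100),
            _row("rs2", 200, SE=0.0),          # nonpositive SE
            _row("rs3", 300, P=0.0),           # p outside (0, 1]
            _row("rs4", 400, EAF=1.0),         # fixed allele
            _row("rs5", 500, A1="A", A2="A"),  # identical alleles
        ]
        ds = read_summary_stats(_write_tsv(tmp_path / "ss.tsv", rows))
        assert list(ds.df["snp_id"]) == ["rs1"]

    def test_shuffled_rows_give_sorted_dataset(self, tmp_path):
        rows = [_row(f"rs{i}", 100 * i) for i in range(1, 20)]
        rng = np.random.default_rng(0)
        shuffled = [rows[i] for i in rng.permutation(len(rows))]
        ds_a = read_summary_stats(_write_tsv(tmp_path / "a.tsv", rows))
        ds_b = read_summary_stats(_write_tsv(tmp_path / "b.tsv", shuffled))
        pd.testing.assert_frame_equal(ds_a.df, ds_b.df)

    def test_missing_column_is_format_error(self, tmp_path):
        df = pd.DataFrame([_row("rs1", 100)]).drop(columns=["SE"])
        path = tmp_path / "bad.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(FormatError):
            read_summary_stats(path)

    def test_zero_valid_rows_is_empty_input_error(self, tmp_path):
        path = _write_tsv(tmp_path / "bad.tsv", [_row("rs1", 100, SE=-1.0)])
        with pytest.raises(EmptyInputError):
            read_summary_stats(path)

    def test_column_map_and_or_scale(self, tmp_path):
        df = pd.DataFrame([_row("rs1", 100, BETA=1.5)]).rename(
            columns={"SNP": "rsid", "BETA": "OR"}
        )
        path = tmp_path / "dialect.tsv"
        df.to_csv(path, sep="\t", index=False)
        ds = read_summary_stats(path, column_map={"SNP": "rsid", "BETA": "OR"},
                                or_scale=True)
        assert ds.df["beta"].iloc[0] == pytest.approx(np.log(1.5))

    def test_write_read_round_trip(self, tmp_path):
        ds = make_dataset([{"pos": p} for p in (100, 200, 300)])
        write_summary_stats(ds, tmp_path / "out.tsv")
        back = read_summary_stats(tmp_path / "out.tsv")
        pd.testing.assert_frame_equal(
            ds.df.reset_index(drop=True), back.df, check_dtype=False
        )


class TestFilters:
    @pytest.mark.parametrize("eaf,kept", [(0.005, False), (0.995, False),
                                          (0.02, True), (0.98, True)])
    def test_maf_filter_is_symmetric(self, eaf, kept):
        ds = make_dataset([{"eaf": eaf}])
        assert (filter_maf(ds, 0.01).n_snps == 1) is kept

    def test_maf_filter_matches_row_by_row_scan(self):
        rng = np.random.default_rng(1)
        eafs = rng.uniform(0.001, 0.999, 200)
        ds = make_dataset([{"eaf": e, "pos": 10 * i + 10} for i, e in enumerate(eafs)])
        kept = set(filter_maf(ds, 0.01).df["snp_id"])
        expect = {
            r.snp_id for r in ds.df.itertuples()
            if min(r.eaf, 1 - r.eaf) > 0.01
        }
        assert kept == expect

    @pytest.mark.parametrize(
        "chrom,pos,removed",
        [
            ("6", 30_000_000, True),    # inside MHC
            ("6", 25_999_999, False),   # just outside
            ("6", 26_000_000, True),    # closed lower boundary
            ("19", 44_400_000, True),   # closed APOE boundary
            ("1", 30_000_000, False),   # wrong chromosome
        ],
    )
    def test_region_masks_closed_intervals(self, chrom, pos, removed):
        ds = make_dataset([{"chrom": chrom, "pos": pos}])
        out = exclude_regions(ds, [MHC_MASK, APOE_MASK])
        assert (out.n_snps == 0) is removed

    def test_bed_region_masks_convert_coordinates(self, tmp_path):
        from pathprs.sumstats import read_region_masks

        path = tmp_path / "masks.bed"
        path.write_text("chr6\t25999999\t34000000\tMHC\n")
        masks = read_region_masks(path)
        assert masks[0].chrom == "6"
        assert masks[0].start_bp == 26_000_000  # 0-based half-open -> 1-based closed
        assert masks[0].end_bp == 34_000_000
        ds = make_dataset([{"chrom": "6", "pos": 26_000_000}])
        assert exclude_regions(ds, masks).n_snps == 0

    def test_filters_are_order_insensitive(self):
        rng = np.random.default_rng(2)
        rows = [{"eaf": e, "pos": int(p)} for e, p in
                zip(rng.uniform(0.001, 0.999, 100), rng.choice(10**6, 100, replace=False))]
        a = make_dataset(rows)
        b = make_dataset(list(reversed(rows)))
        # same snp ids under both orders after renumbering by content
        fa = filter_maf(a, 0.01)
        fb = filter_maf(b, 0.01)
        assert set(map(tuple, fa.df[["pos", "eaf"]].values.tolist())) == set(
            map(tuple, fb.df[["pos", "eaf"]].values.tolist())
        )


class TestHarmonize:
    def _pair(self, disc_rows, targ_rows):
        return make_dataset(disc_rows, "d"), make_dataset(targ_rows, "t")

    def test_identical_alleles_pass_through(self):
        d, t = self._pair([{"beta": 0.1}], [{"beta": -0.05}])
        out = harmonize(d, t)
        assert out.df["w"].iloc[0] == pytest.approx(0.1)
        assert out.df["b"].iloc[0] == pytest.approx(-0.05)

    def test_swapped_alleles_flip_target_sign(self):
        d, t = self._pair(
            [{"effect_allele": "A", "other_allele": "G", "beta": 0.1}],
            [{"effect_allele": "G", "other_allele": "A", "beta": -0.05}],
        )
        assert harmonize(d, t).df["b"].iloc[0] == pytest.approx(0.05)

    def test_strand_flip_resolved(self):
        d, t = self._pair(
            [{"effect_allele": "A", "other_allele": "G", "beta": 0.1}],
            [{"effect_allele": "T", "other_allele": "C", "beta": -0.05}],
        )
        assert harmonize(d, t).df["b"].iloc[0] == pytest.approx(-0.05)

    def test_protective_allele_oriented_to_risk(self):
        d, t = self._pair([{"beta": -0.1, "eaf": 0.3}], [{"beta": 0.02}])
        out = harmonize(d, t)
        assert out.df["w"].iloc[0] == pytest.approx(0.1)
        assert out.df["b"].iloc[0] == pytest.approx(-0.02)
        assert out.df["eaf"].iloc[0] == pytest.approx(0.7)

    def test_palindromic_snps_dropped_by_default(self):
        d, t = self._pair(
            [{"effect_allele": "A", "other_allele": "T"}, {"pos": 2000}],
            [{"effect_allele": "A", "other_allele": "T"}, {"pos": 2000}],
        )
        out = harmonize(d, t)
        assert list(out.df["snp_id"]) == ["rs2"]

    def test_palindromic_rescue_by_frequency(self):
        d, t = self._pair(
            [{"effect_allele": "A", "other_allele": "T", "eaf": 0.2}],
            [{"effect_allele": "A", "other_allele": "T", "eaf": 0.22, "beta": 0.05}],
        )
        out = harmonize(d, t, rescue_palindromic=True)
        assert out.n_snps == 1
        assert out.df["b"].iloc[0] == pytest.approx(0.05)

    def test_orientation_is_idempotent(self):
        rng = np.random.default_rng(3)
        rows = [{"beta": float(b), "pos": 100 * (i + 1)}
                for i, b in enumerate(rng.normal(0, 0.1, 30))]
        d, t = self._pair(rows, [{"pos": 100 * (i + 1)} for i in range(30)])
        once = harmonize(d, t)
        assert (once.df["w"] >= 0).all()
        # re-orienting an already oriented table changes nothing
        flipped = once.df.copy()
        neg = flipped["w"] < 0
        assert not neg.any()

    def test_empty_overlap_raises(self):
        d = make_dataset([{}])
        t = make_dataset([{}])
        t = t.copy()
        t.df["snp_id"] = ["other"]
        with pytest.raises(EmptyOverlapError):
            harmonize(d, t)

    def test_build_mismatch_is_hard_error(self):
        d = make_dataset([{}])
        t = make_dataset([{}])
        t.build_tag = "GRCh38"
        with pytest.raises(BuildMismatchError):
            harmonize(d, t)


class TestBilateral:
    def test_perfectly_correlated_duplicate_is_identity(self):
        left = make_dataset([{"beta": 1.0, "se": 1.0}])
        right = make_dataset([{"beta": 1.0, "se": 1.0}])
        out = average_bilateral(left, right, rho=1.0)
        assert out.df["beta"].iloc[0] == pytest.approx(1.0)
        assert out.df["se"].iloc[0] == pytest.approx(1.0)

    def test_anticorrelated_closed_form(self):
        left = make_dataset([{"beta": 1.0, "se": 1.0}])
        right = make_dataset([{"beta": -1.0, "se": 1.0}])
        out = average_bilateral(left, right, rho=0.0)
        assert out.df["beta"].iloc[0] == pytest.approx(0.0)
        assert out.df["se"].iloc[0] == pytest.approx(np.sqrt(2) / 2)

    def test_monte_carlo_se_formula(self):
        # simulate correlated (bL, bR) pairs; empirical SD of the average
        # must match the analytic SE within 5%
        rng = np.random.default_rng(4)
        rho, sl, sr = 0.6, 0.8, 1.2
        cov = [[sl**2, rho * sl * sr], [rho * sl * sr, sr**2]]
        draws = rng.multivariate_normal([0, 0], cov, size=2000)
        avg = draws.mean(axis=1)
        expect = np.sqrt(sl**2 + sr**2 + 2 * rho * sl * sr) / 2
        assert np.std(avg) == pytest.approx(expect, rel=0.05)

    def test_rho_estimated_from_null_snps(self):
        rng = np.random.default_rng(5)
        n = 3000
        rho = 0.5
        zl = rng.standard_normal(n)
        zr = rho * zl + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        rows_l = [{"pos": 10 * i + 10, "beta": 0.1 * zl[i], "se": 0.1,
                   "pvalue": float(2 * stats.norm.sf(abs(zl[i])))} for i in range(n)]
        rows_r = [{"pos": 10 * i + 10, "beta": 0.1 * zr[i], "se": 0.1,
                   "pvalue": float(2 * stats.norm.sf(abs(zr[i])))} for i in range(n)]
        out = average_bilateral(make_dataset(rows_l), make_dataset(rows_r))
        # beta = (bl+br)/2 always; the estimated rho shows up in the SE
        implied_rho = (2 * out.df["se"].iloc[0]) ** 2 / 0.01 - 2
        assert implied_rho / 2 == pytest.approx(rho, abs=0.15)


class TestMeta:
    def test_equal_weights_give_mean(self):
        a = make_dataset([{"beta": 0.1, "se": 0.05}])
        b = make_dataset([{"beta": 0.3, "se": 0.05}])
        out = meta_snp([a, b])
        assert out.df["beta"].iloc[0] == pytest.approx(0.2)

    def test_single_cohort_snp_passes_through_flagged(self):
        a = make_dataset([{}, {"pos": 2000}])
        b = make_dataset([{}])
        out = meta_snp([a, b])
        row = out.df.set_index("snp_id").loc["rs2"]
        assert row["n_studies"] == 1
        assert row["beta"] == pytest.approx(0.1)
        assert row["se"] == pytest.approx(0.05)

    def test_three_cohort_weighted_mean_oracle(self):
        rng = np.random.default_rng(6)
        betas = rng.normal(0, 0.1, 3)
        ses = rng.uniform(0.02, 0.1, 3)
        dsets = [make_dataset([{"beta": float(b), "se": float(s)}])
                 for b, s in zip(betas, ses)]
        out = meta_snp(dsets)
        w = 1 / ses**2
        assert out.df["beta"].iloc[0] == pytest.approx(np.sum(w * betas) / np.sum(w), abs=1e-12)
        assert out.df["se"].iloc[0] == pytest.approx(np.sum(w) ** -0.5, abs=1e-12)

    def test_standardize_rescales_units_consistently(self):
        # same z in different trait units must pool to the same z
        a = make_dataset([{"beta": 26.9, "se": 10.0}])
        b = make_dataset([{"beta": 0.05, "se": 0.0186}])
        out = meta_snp([a, b], standardize=True)
        z = out.df["beta"] / out.df["se"]
        za, zb = 26.9 / 10.0, 0.05 / 0.0186
        assert float(z.iloc[0]) == pytest.approx((za + zb) / np.sqrt(2), rel=0.01)

    def test_meta_snp_of_duplicated_dataset_scales_se(self):
        a = make_dataset([{"beta": 0.2, "se": 0.04}])
        out = meta_snp([a, a.copy()])
        assert out.df["beta"].iloc[0] == pytest.approx(0.2)
        assert out.df["se"].iloc[0] == pytest.approx(0.04 / np.sqrt(2))

    def test_meta_estimates_identity_and_closed_form(self):
        one = meta_estimates([(0.5, 0.1)])
        assert (one.estimate, one.se) == (0.5, 0.1)
        two = meta_estimates([(1.0, 1.0), (3.0, 1.0)])
        assert two.estimate == pytest.approx(2.0)
        assert two.se == pytest.approx(np.sqrt(2) / 2)
        assert two.z == pytest.approx(two.estimate / two.se)

    def test_repeated_inputs_shrink_se_by_sqrt_k(self):
        k = 4
        out = meta_estimates([(0.3, 0.12)] * k)
        assert out.estimate == pytest.approx(0.3)
        assert out.se == pytest.approx(0.12 / np.sqrt(k))

    def test_dersimonian_laird_matches_hand_computation(self):
        est = np.array([0.2, 0.5, -0.1, 0.4, 0.15])
        se = np.array([0.1, 0.15, 0.2, 0.12, 0.18])
        w = 1 / se**2
        mu_f = np.sum(w * est) / np.sum(w)
        q = np.sum(w * (est - mu_f) ** 2)
        c = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - 4) / c)
        wr = 1 / (se**2 + tau2)
        expect = np.sum(wr * est) / np.sum(wr)
        out = meta_estimates(list(zip(est, se)), method="random_dl")
        assert out.tau2 == pytest.approx(tau2, abs=1e-12)
        assert out.estimate == pytest.approx(expect, abs=1e-12)
        assert out.se == pytest.approx(np.sum(wr) ** -0.5, abs=1e-12)
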