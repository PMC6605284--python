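"""Reference panel loading, LD computation and greedy clumping."""

import numpy as np
import pandas as pd
import pytest

from pathprs.errors import FormatError, PanelLookupError
from pathprs.ldpanel import ClumpParams, ReferencePanel, clump, ld_r2, load_panel
from pathprs.sumstats import AlignedScoreTable

from conftest import random_aligned_frame

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
)


def _write_vcf(path, body):
    path.write_text(VCF_HEADER + body)
    return path


class TestLoadPanel:
    def test_additive_dosage_coding(self, tmp_path):
        vcf = _write_vcf(
            tmp_path / "p.vcf",
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n",
        )
        panel = load_panel(vcf)
        assert panel.n_snps == 1
        np.testing.assert_array_equal(panel.column("rs1"), [0.0, 1.0, 2.0])

    def test_monomorphic_site_dropped(self, tmp_path):
        vcf = _write_vcf(
            tmp_path / "p.vcf",
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0\n"
            "1\t200\trs2\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n",
        )
        panel = load_panel(vcf)
        assert list(panel.snp_meta["snp_id"]) == ["rs2"]

    def test_multiallelic_site_dropped(self, tmp_path):
        vcf = _write_vcf(
            tmp_path / "p.vcf",
            "1\t100\trs1\tA\tG,T\t.\tPASS\t.\tGT\t0/0\t0/1\t1/2\n"
            "1\t200\trs2\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n",
        )
        panel = load_panel(vcf)
        assert "rs1" not in panel
        assert "rs2" in panel

    def test_unreadable_vcf_is_format_error(self, tmp_path):
        bad = tmp_path / "nope.vcf"
        bad.write_text("this is not a vcf\n")
        with pytest.raises(FormatError):
            load_panel(bad)


def _panel_from_matrix(dosages, positions=None, chrom="1"):
    n = dosages.shape[1]
    positions = positions if positions is not None else (np.arange(n) + 1) * 1000
    meta = pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(n)],
            "chrom": chrom,
            "pos": positions,
            "ref_allele": "A",
            "alt_allele": "G",
        }
    )
    return ReferencePanel(np.asarray(dosages, dtype=float), meta)


class TestLdR2:
    def test_self_correlation_is_one(self):
        panel = _panel_from_matrix(np.array([[0, 1], [1, 0], [2, 2], [1, 1]]))
        assert ld_r2(panel, "rs0", "rs0") == pytest.approx(1.0)

    def test_hand_computed_dosage_pair(self):
        a = np.array([0, 1, 2, 1])
        b = np.array([0, 1, 2, 2])
        panel = _panel_from_matrix(np.column_stack([a, b]))
        expect = np.corrcoef(a, b)[0, 1] ** 2
        assert ld_r2(panel, "rs0", "rs1") == pytest.approx(expect, abs=1e-12)
        # direct arithmetic on the same definition
        ra = (np.mean(a * b) - a.mean() * b.mean()) / (a.std() * b.std())
        assert ld_r2(panel, "rs0", "rs1") == pytest.approx(ra**2, abs=1e-12)

    def test_independent_columns_have_tiny_r2(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 3, size=(500, 2)).astype(float)
        base[:, 1] = rng.permutation(base[:, 1])
        panel = _panel_from_matrix(base)
        assert ld_r2(panel, "rs0", "rs1") < 0.02

    def test_unknown_snp_raises(self):
        panel = _panel_from_matrix(np.array([[0.0], [1.0], [2.0]]))
        with pytest.raises(PanelLookupError):
            ld_r2(panel, "rs0", "missing")


def brute_force_clump(aligned, panel, params):
    """Independent reference implementation: explicit pairwise loops."""
    df = aligned.df.loc[aligned.df["snp_id"].map(lambda s: s in panel)]
    order = df.sort_values(["p_disc", "chrom", "pos", "snp_id"])
    assigned = {}
    index = []
    taken = set()
    for row in order.itertuples():
        if row.snp_id in taken or row.p_disc > params.p1:
            continue
        index.append(row.snp_id)
        taken.add(row.snp_id)
        for other in order.itertuples():
            if other.snp_id in taken or other.p_disc > params.p2:
                continue
            if other.chrom != row.chrom:
                continue
            if abs(other.pos - row.pos) > params.window_kb * 1000:
                continue
            if ld_r2(panel, row.snp_id, other.snp_id) >= params.r2_threshold:
                assigned[other.snp_id] = row.snp_id
                taken.add(other.snp_id)
    return index, assigned


def _ld_fixture(seed, n=120, n_blocks=6, rho=0.5, samples=150):
    """Correlated-block dosages plus an aligned table, for clump tests."""
    rng = np.random.default_rng(seed)
    m = n // n_blocks
    cols = []
    for _ in range(n_blocks):
        shared = rng.standard_normal((samples, 1))
        lat = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal((samples, m))
        f = rng.uniform(0.1, 0.5, m)
        thr = np.quantile(lat, f, axis=0).diagonal()
        cols.append((lat < thr).astype(float) + (rng.permutation(lat) < thr))
    dosages = np.concatenate(cols, axis=1)
    keep = dosages.std(axis=0) > 0
    dosages = dosages[:, keep]
    positions = ((np.arange(n) + 1) * 40_000)[keep]
    panel = _panel_from_matrix(dosages, positions)
    aligned = random_aligned_frame(rng, n=keep.sum())
    aligned.df["pos"] = positions
    aligned.df["snp_id"] = panel.snp_meta["snp_id"].to_numpy()
    return aligned, panel


class TestClump:
    def test_single_snp_is_sole_index(self):
        panel = _panel_from_matrix(np.array([[0.0], [1.0], [2.0], [1.0]]))
        df = pd.DataFrame(
            [{"snp_id": "rs0", "chrom": "1", "pos": 1000, "w": 0.1, "b": 0.0,
              "s": 0.05, "p_disc": 0.01, "p_targ": 0.5, "eaf": 0.3}]
        )
        res = clump(AlignedScoreTable(df, 1000), panel)
        assert res.index_snps == ["rs0"]
        assert res.assignments == {}

    def test_greedy_keeps_most_significant_of_pair(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 3, 200).astype(float)
        noise = rng.random(200) < 0.05
        b = np.where(noise, rng.integers(0, 3, 200), a).astype(float)
        panel = _panel_from_matrix(np.column_stack([a, b]), positions=[1000, 11_000])
        df = pd.DataFrame(
            {
                "snp_id": ["rs0", "rs1"],
                "chrom": "1",
                "pos": [1000, 11_000],
                "w": 0.1, "b": 0.0, "s": 0.05,
                "p_disc": [1e-2, 1e-4],
                "p_targ": 0.5, "eaf": 0.3,
            }
        )
        res = clump(AlignedScoreTable(df, 1000), panel)
        assert res.index_snps == ["rs1"]
        assert res.assignments == {"rs0": "rs1"}

    def test_matches_brute_force_oracle(self):
        params = ClumpParams()
        for seed in range(4):
            aligned, panel = _ld_fixture(seed)
            res = clump(aligned, panel, params)
            idx, asg = brute_force_clump(aligned, panel, params)
            assert res.index_snps == idx
            assert res.assignments == asg

    def test_postconditions_and_determinism(self):
        aligned, panel = _ld_fixture(10)
        params = ClumpParams()
        res = clump(aligned, panel, params)
        pmap = aligned.df.set_index("snp_id")["p_disc"]
        posmap = aligned.df.set_index("snp_id")["pos"]
        # assigned SNP p >= index SNP p, same chromosome within window
        for removed, idx in res.assignments.items():
            assert pmap[removed] >= pmap[idx]
            assert abs(posmap[removed] - posmap[idx]) <= params.window_kb * 1000
        # no two index SNPs within the window share r2 >= threshold
        for i, a in enumerate(res.index_snps):
            for b in res.index_snps[i + 1:]:
                if abs(posmap[a] - posmap[b]) <= params.window_kb * 1000:
                    assert ld_r2(panel, a, b) < params.r2_threshold
        # permuting input row order changes nothing
        shuffled = aligned.copy()
        shuffled.df = shuffled.df.sample(frac=1, random_state=3).reset_index(drop=True)
        assert clump(shuffled, panel, params).index_snps == res.index_snps

    def test_raising_r2_threshold_never_loses_index_snps(self):
        aligned, panel = _ld_fixture(11)
        counts = [
            clump(aligned, panel, ClumpParams(r2_threshold=r2)).n_index
            for r2 in (0.05, 0.2, 0.5, 0.8)
        ]
        assert counts == sorted(counts)

    def test_snps_missing_from_panel_are_excluded(self):
        aligned, panel = _ld_fixture(12)
        extra = aligned.df.iloc[[0]].assign(snp_id="rs_not_in_panel", pos=999_999)
        aligned.df = pd.concat([aligned.df, extra], ignore_index=True)
        res = clump(aligned, panel)
        assert res.n_missing_panel == 1
        assert "rs_not_in_panel" not in res.index_snps
        assert "rs_not_in_panel" not in res.assignments
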