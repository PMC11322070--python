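import numpy as np
import pandas as pd
import pytest

from mppqei.core_data import GeneticMap
from mppqei.scan import (ScanConfig, ScanData, assemble_final_model,
                         bonferroni_threshold, forward_select, genome_scan,
                         report)
from mppqei.simulate import TrueQTL
from tests.conftest import make_diallel_sim

TWO_CHROM = GeneticMap.from_rows([("1", 0.0), ("1", 80.0), ("2", 0.0), ("2", 80.0)])
FAST = ScanConfig(polygenic=("us", "idh"), max_rounds=4)


class TestThreshold:
    @pytest.mark.parametrize("n,alpha,expected", [
        (1, 0.05, 1.3010300),
        (500, 0.05, 4.0),
        (1000, 0.05, 4.3010300),
    ])
    def test_values(self, n, alpha, expected):
        assert bonferroni_threshold(n, alpha) == pytest.approx(expected, abs=1e-6)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(10, 1.5)


@pytest.fixture(scope="module")
def qtl_sim():
    return make_diallel_sim(
        seed=101, n_per_family=40, gmap=TWO_CHROM, grid_step=5.0,
        qtls=[TrueQTL("1", 40.0, "ecfc", variance=2.0)])


class TestGenomeScan:
    def test_masking_rule(self, qtl_sim):
        data = ScanData(qtl_sim.ibd, qtl_sim.obs)
        ci = qtl_sim.ibd.grid.index_of("1", 40.0)
        prof = genome_scan(data, "ecfc", [ci], FAST)
        t = prof.table
        on1 = t["chrom"] == "1"
        inside = on1 & (t["pos_cM"] >= 30.0) & (t["pos_cM"] <= 50.0)
        assert t.loc[inside, "masked"].all()
        assert not t.loc[~inside, "masked"].any()
        assert t.loc[inside, "neglog10p"].isna().all()

    def test_monotone_masking(self, qtl_sim):
        data = ScanData(qtl_sim.ibd, qtl_sim.obs)
        c1 = qtl_sim.ibd.grid.index_of("1", 40.0)
        c2 = qtl_sim.ibd.grid.index_of("2", 20.0)
        m1 = genome_scan(data, "ecfc", [c1], FAST).table["masked"]
        m2 = genome_scan(data, "ecfc", [c1, c2], FAST).table["masked"]
        assert (m2 | ~m1).all()  # previously masked positions stay masked

    def test_profile_peak_near_simulated_qtl(self, qtl_sim):
        data = ScanData(qtl_sim.ibd, qtl_sim.obs)
        prof = genome_scan(data, "ecfc", [], FAST)
        idx, peak = prof.peak()
        row = prof.table.iloc[idx]
        assert row["chrom"] == "1"
        assert abs(row["pos_cM"] - 40.0) <= 10.0
        assert peak > prof.threshold

    def test_full_reml_scan_agrees_with_profiled_shortcut(self):
        # joint refits per position give at-least-as-large statistics but
        # the same peak location for a clear signal
        sim = make_diallel_sim(
            seed=105, n_per_family=20,
            gmap=GeneticMap.from_rows([("1", 0.0), ("1", 60.0)]),
            grid_step=10.0,
            qtls=[TrueQTL("1", 30.0, "ecfc", variance=3.0)])
        data = ScanData(sim.ibd, sim.obs)
        short = genome_scan(data, "ecfc", [], FAST)
        full = genome_scan(data, "ecfc", [],
                           ScanConfig(polygenic=("us", "idh"), full_reml=True))
        i1, _ = short.peak()
        i2, _ = full.peak()
        assert abs(short.table.iloc[i1]["pos_cM"]
                   - full.table.iloc[i2]["pos_cM"]) <= 10.0
        ok = full.table["converged"] & short.table["converged"]
        diff = (full.table.loc[ok, "stat"] - short.table.loc[ok, "stat"])
        assert (diff > -0.05).all()

    def test_scan_is_deterministic(self, qtl_sim):
        data = ScanData(qtl_sim.ibd, qtl_sim.obs)
        p1 = genome_scan(data, "esfc", [], FAST).table
        p2 = genome_scan(data, "esfc", [], FAST).table
        pd.testing.assert_frame_equal(p1, p2)


class TestForwardSelect:
    def test_strong_qtl_recovered_as_cofactor(self, qtl_sim):
        data = ScanData(qtl_sim.ibd, qtl_sim.obs)
        cofs, prof, peaks = forward_select(data, "ecfc", FAST)
        assert len(cofs) >= 1
        top = data.grid.table.iloc[cofs[0]]
        assert top["chrom"] == "1"
        assert abs(top["pos_cM"] - 40.0) <= 10.0

    def test_close_qtls_yield_single_cofactor_in_window(self):
        sim = make_diallel_sim(
            seed=103, n_per_family=40, gmap=TWO_CHROM, grid_step=5.0,
            qtls=[TrueQTL("1", 40.0, "ecfc", variance=2.0),
                  TrueQTL("1", 45.0, "ecfc", variance=2.0)])
        data = ScanData(sim.ibd, sim.obs)
        cofs, _, _ = forward_select(data, "ecfc", FAST)
        pos = data.grid.table.iloc[cofs]
        # the 20 cM exclusion window forbids a second cofactor within the
        # first hit's window, so the twin QTL cannot be selected separately
        near = pos[(pos["chrom"] == "1") & (pos["pos_cM"] >= 32.5)
                   & (pos["pos_cM"] <= 52.5)]
        assert len(near) <= 1
        on1 = np.sort(pos.loc[pos["chrom"] == "1", "pos_cM"].to_numpy())
        if len(on1) > 1:
            assert np.diff(on1).min() > 10.0


class TestMagicScan:
    def test_magic_scan_detects_qtl_with_env_types_only(self):
        from mppqei.core_data import PopulationDesign
        from mppqei.simulate import PolygenicSpec, SimulationConfig, simulate_dataset
        founders = [f"F{i}" for i in range(8)]
        design = PopulationDesign.magic_funnel(founders, selfing_generations=4)
        gmap = GeneticMap.from_rows([("1", 0.0), ("1", 60.0)])
        effects = np.zeros(8)
        effects[:4] = 2.0
        effects[4:] = -2.0
        cfg = SimulationConfig(
            design=design, gmap=gmap, n_per_family=60, n_env=2,
            qtls=[TrueQTL("1", 30.0, "ecfc", effects=effects)],
            polygenic=PolygenicSpec.from_corr([0.3, 0.3], 0.5,
                                              mpp_weights=[1.0]),
            residual_var=[0.5, 0.5], grid_step=10.0, seed=7)
        sim = simulate_dataset(cfg)
        data = ScanData(sim.ibd, sim.obs)
        cofs, prof, peaks = forward_select(data, "ecfc", FAST)
        assert cofs, "strong MAGIC QTL not detected"
        top = data.grid.table.iloc[cofs[int(np.argmax(peaks))]]
        assert abs(top["pos_cM"] - 30.0) <= 10.0
        per_type = {"ecfc": (cofs, prof, peaks)}
        records, _ = assemble_final_model(per_type, data, FAST)
        # family-specific formulations are not in the MAGIC candidate set
        assert records[0].effect_type in ("ecfc", "esfc")


class TestAssemble:
    def test_locus_found_by_multiple_scans_merges_to_one_record(self, qtl_sim):
        data = ScanData(qtl_sim.ibd, qtl_sim.obs)
        per_type = {et: forward_select(data, et, FAST)
                    for et in ("ecfc", "esfc")}
        n_hits = sum(len(v[0]) for v in per_type.values())
        records, final_fit = assemble_final_model(per_type, data, FAST)
        chr1 = [r for r in records if r.chrom == "1"
                and abs(r.pos_cM - 40.0) <= 10.0]
        assert len(chr1) == 1
        assert n_hits >= 2  # both scans saw it, yet a single record remains
        rec = chr1[0]
        assert rec.peak_neglog10p > bonferroni_threshold(
            data.grid.n_positions, FAST.alpha)
        assert rec.effects is not None and "blup" in rec.effects

    def test_no_hits_gives_empty_result(self):
        sim = make_diallel_sim(seed=104, n_per_family=15, grid_step=25.0)
        data = ScanData(sim.ibd, sim.obs)
        records, fit = assemble_final_model(
            {"ecfc": ([], None, [])}, data, FAST)
        assert records == [] and fit is None


class TestReport:
    def test_report_round_trip(self, qtl_sim, tmp_path):
        data = ScanData(qtl_sim.ibd, qtl_sim.obs)
        per_type = {"ecfc": forward_select(data, "ecfc", FAST)}
        records, _ = assemble_final_model(per_type, data, FAST)
        written = report(records, {"ecfc": per_type["ecfc"][1]}, tmp_path)
        prof = pd.read_csv(written["profile_ecfc"])
        orig = per_type["ecfc"][1].table
        np.testing.assert_allclose(
            prof["neglog10p"].to_numpy(), orig["neglog10p"].to_numpy(),
            atol=1e-12)
        recs = pd.read_csv(written["qtl_records"])
        assert len(recs) == len(records)
        heat = pd.read_csv(written["effects_heat"])
        assert len(heat) > 0

    def test_empty_records_still_write_headers(self, tmp_path):
        written = report([], {}, tmp_path)
        recs = pd.read_csv(written["qtl_records"])
        assert list(recs.columns) == ["chrom", "pos_cM", "effect_type",
                                      "peak_neglog10p", "found_by"]
        assert recs.empty
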