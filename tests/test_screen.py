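import json
import random

import numpy as np
import pytest

from fragscreen.chemio import parse_smiles, write_smiles
from fragscreen.fixtures import gen_random_library, write_labels
from fragscreen.screen import (ZHAO_ATOM_VOLUMES, CutoffConfig, apply_cutoff,
                               enrichment_factor, max_tanimoto, morgan_fp,
                               nested_screen, run_pipeline, zhao_volume)

from .oracles import brute_force_ef, independent_zhao


class TestZhaoVolume:
    def test_methane(self):
        assert zhao_volume(parse_smiles("C")) == pytest.approx(
            20.58 + 4 * 7.24 - 5.92 * 4, abs=1e-9)

    def test_benzene(self):
        assert zhao_volume(parse_smiles("c1ccccc1")) == pytest.approx(
            6 * 20.58 + 6 * 7.24 - 5.92 * 12 - 14.7, abs=1e-9)

    def test_ch2_homologation_increment(self):
        # one more C, two more H, three more bonds (C-C plus two C-H, with
        # one former C-H replaced and one added back)
        delta = zhao_volume(parse_smiles("CCCC")) - zhao_volume(parse_smiles("CCC"))
        assert delta == pytest.approx(20.58 + 2 * 7.24 - 5.92 * 3, abs=1e-9)

    def test_matches_independent_oracle_on_random_molecules(self):
        for m in gen_random_library(100, seed=41):
            assert zhao_volume(m) == pytest.approx(independent_zhao(m), abs=1e-9)

    def test_unknown_element_named(self):
        with pytest.raises(ValueError, match="Ge"):
            zhao_volume(parse_smiles("[GeH4]"))


class TestCutoff:
    def test_boundary_rules(self):
        cfg = CutoffConfig(vp=250.0, k=1.5)
        benzene = parse_smiles("c1ccccc1", id="bz")  # Vc ~ 81.2: kept
        assert apply_cutoff([benzene], cfg) == (["bz"], [])
        tiny = CutoffConfig(vp=zhao_volume(benzene) / 1.5, k=1.5)
        assert apply_cutoff([benzene], tiny) == (["bz"], [])  # Vc == k*Vp kept
        below = CutoffConfig(vp=zhao_volume(benzene) / 1.5 - 1e-6, k=1.5)
        assert apply_cutoff([benzene], below) == ([], ["bz"])

    def test_kept_set_monotone_in_k(self):
        mols = gen_random_library(60, seed=43)
        vp = 100.0
        prev: set = set()
        for k in (0.5, 1.0, 1.5, 2.5, 5.0, 1e6):
            kept = set(apply_cutoff(mols, CutoffConfig(vp=vp, k=k))[0])
            assert prev <= kept
            prev = kept
        assert prev == {m.id for m in mols}  # k -> inf keeps everything
        assert apply_cutoff(mols, CutoffConfig(vp=vp, k=1e-9))[0] == []

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            CutoffConfig(vp=-1.0)


class TestEnrichmentFactor:
    def test_worked_example(self):
        n, n_act = 1000, 10
        actives = {f"a{i}" for i in range(n_act)}
        ranked = [f"a{i}" for i in range(5)] + \
                 [f"d{i}" for i in range(n - n_act)] + \
                 [f"a{i}" for i in range(5, n_act)]
        assert enrichment_factor(ranked, actives, 0.01) == pytest.approx(50.0)

    def test_full_fraction_is_unity(self):
        ranked = ["a", "b", "c", "d"]
        assert enrichment_factor(ranked, {"b"}, 1.0) == pytest.approx(1.0)

    def test_no_actives_in_top(self):
        ranked = ["d0", "d1", "a0"]
        assert enrichment_factor(ranked, {"a0"}, 1 / 3) == 0.0

    def test_no_actives_at_all_errors(self):
        with pytest.raises(ValueError, match="EF undefined"):
            enrichment_factor(["d0", "d1"], {"x"}, 0.5)

    def test_agrees_with_brute_force_on_permutations(self):
        rng = random.Random(7)
        ids = [f"c{i}" for i in range(400)]
        actives = set(rng.sample(ids, 25))
        for _ in range(200):
            rng.shuffle(ids)
            for frac in (0.01, 0.02, 0.1, 0.5, 1.0):
                assert enrichment_factor(ids, actives, frac) == pytest.approx(
                    brute_force_ef(ids, actives, frac))

    def test_bounds_on_random_permutations(self):
        rng = random.Random(13)
        ids = [f"c{i}" for i in range(500)]
        actives = set(rng.sample(ids, 20))
        for _ in range(1000):
            rng.shuffle(ids)
            for frac in (0.01, 0.05, 0.2):
                ef = enrichment_factor(ids, actives, frac)
                assert 0.0 <= ef <= min(1 / frac, len(ids) / len(actives)) + 1e-9


class TestNestedScreen:
    def setup_method(self):
        rng = random.Random(3)
        self.ids = [f"c{i}" for i in range(300)]
        self.actives = set(rng.sample(self.ids, 12))
        self.pre = {cid: rng.uniform(0, 10) for cid in self.ids}
        self.re = {cid: rng.uniform(0, 10) for cid in self.ids}

    def test_degenerate_prescreen_equals_plain_ef(self):
        from fragscreen.scoring import rank_compounds
        ranked = [cid for cid, _, _ in rank_compounds(self.re)]
        assert nested_screen(self.pre, self.re, 1.0, 0.02, self.actives) == \
            pytest.approx(enrichment_factor(ranked, self.actives, 0.02))

    def test_prescreen_dropping_all_actives_zeroes_ef(self):
        pre = {cid: (0.0 if cid in self.actives else 1.0) for cid in self.ids}
        re = {cid: (10.0 if cid in self.actives else 0.0) for cid in self.ids}
        assert nested_screen(pre, re, 0.05, 0.02, self.actives) == 0.0

    def test_perfect_stages_reach_maximum(self):
        # with Pos_100 = 12 = floor(0.04 * 300) = All_b, a perfect screen
        # fills the top-b window with actives exactly: EF = All_100 / Pos_100
        pre = {cid: (10.0 if cid in self.actives else 0.0) for cid in self.ids}
        ef = nested_screen(pre, pre, 0.1, 0.04, self.actives)
        assert ef == pytest.approx(len(self.ids) / len(self.actives))

    def test_b_greater_than_a_errors(self):
        with pytest.raises(ValueError):
            nested_screen(self.pre, self.re, 0.01, 0.02, self.actives)


class TestTanimoto:
    def test_identity_and_disjoint(self):
        q = morgan_fp(parse_smiles("c1ccccc1"))
        refs = [morgan_fp(parse_smiles(s)) for s in ("c1ccccc1", "C1CCOC1")]
        assert max_tanimoto(q, refs) == 1.0
        assert max_tanimoto(morgan_fp(parse_smiles("CCCCCC")),
                            [morgan_fp(parse_smiles("c1ccncc1"))]) < 0.1

    def test_singleton_matches_bitwise_brute_force(self):
        q = morgan_fp(parse_smiles("CC(=O)Nc1ccc(O)cc1"))
        r = morgan_fp(parse_smiles("CC(=O)Nc1ccccc1"))
        qa, ra = set(q.GetOnBits()), set(r.GetOnBits())
        expected = len(qa & ra) / len(qa | ra)
        assert max_tanimoto(q, [r]) == pytest.approx(expected)

    def test_empty_refs_error(self):
        with pytest.raises(ValueError):
            max_tanimoto(morgan_fp(parse_smiles("C")), [])


class TestPipeline:
    @pytest.fixture()
    def setup_run(self, tmp_path, benchmark):
        lib_path = tmp_path / "library.smi"
        labels_path = tmp_path / "labels.tsv"
        write_smiles(benchmark.molecules, lib_path)
        write_labels(benchmark.labels, labels_path)
        from fragscreen.docking import write_scores
        scores_path = tmp_path / "scores.tsv"
        write_scores(benchmark.score_table, scores_path)
        return {"library": str(lib_path), "scores": str(scores_path),
                "labels": str(labels_path), "formula": "gs", "x": 3,
                "vp": 400.0, "k": 1.5, "fractions": [0.01, 0.02], "seed": 5}

    def test_report_schema(self, tmp_path, setup_run, benchmark):
        report = run_pipeline(setup_run, out_dir=tmp_path / "out")
        assert set(report.enrichment) == {"EF1%", "EF2%"}
        assert all(v >= 0 for v in report.enrichment.values())
        ranked = [r for r in report.compounds.values() if r["rank"] is not None]
        assert len(ranked) + report.n_omitted == len(benchmark.molecules)
        payload = json.loads((tmp_path / "out" / "report.json").read_text())
        assert payload["formula"] == "gs" and payload["gs_exponent"] == 3
        ranking = (tmp_path / "out" / "ranking.tsv").read_text().splitlines()
        assert ranking[0].startswith("compound_id\tscore\trank")

    def test_rerun_is_byte_identical(self, tmp_path, setup_run):
        run_pipeline(setup_run, out_dir=tmp_path / "r1")
        run_pipeline(setup_run, out_dir=tmp_path / "r2")
        for name in ("report.json", "ranking.tsv"):
            assert (tmp_path / "r1" / name).read_bytes() == \
                (tmp_path / "r2" / name).read_bytes()

    def test_labels_optional(self, tmp_path, setup_run):
        cfg = {k: v for k, v in setup_run.items() if k != "labels"}
        report = run_pipeline(cfg, out_dir=tmp_path / "out2")
        assert report.enrichment == {}
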