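"""Window filtering, clustering, energy ranking and the full pipeline."""

import json

import numpy as np
import pytest

from fretscreen import io as fio
from fretscreen import screening as sc
from fretscreen import synthetic_data as sd
from fretscreen.structure import SitePair


def planted_distance(manifest, model_id):
    return next(p["dda_nm"] for p in manifest["poses"] if p["model_id"] == model_id)


class TestEnsembleDistances:
    def test_every_model_measured_in_rank_order(self, planted_ensemble):
        ensemble, manifest = planted_ensemble
        distances = sc.measure_ensemble_dda(ensemble)
        assert list(distances) == [m.model_id for m in ensemble.models]
        assert len(distances) == manifest["n_poses"] == 50

    def test_distances_match_planted_values(self, planted_ensemble):
        ensemble, manifest = planted_ensemble
        distances = sc.measure_ensemble_dda(ensemble)
        for mid, d in distances.items():
            assert d == pytest.approx(planted_distance(manifest, mid), abs=1e-6)

    def test_missing_donor_names_offending_model(self, planted_ensemble):
        ensemble, _ = planted_ensemble
        bad_sites = SitePair("A", 999, "B")
        broken = sc.PoseEnsemble(models=ensemble.models, sites=bad_sites)
        with pytest.raises(ValueError, match="pose_"):
            sc.measure_ensemble_dda(broken)


class TestWindow:
    def test_reported_distance_gives_reported_window(self):
        w = sc.window_from_fret(3.9, 0.3, linker_offset=0.1)
        assert w.low == pytest.approx(3.7)
        assert w.high == pytest.approx(4.3)

    def test_bounds_are_inclusive(self):
        w = sc.window_from_fret(3.9, 0.3, linker_offset=0.1)
        assert w.contains(3.7) and w.contains(4.3)
        assert not w.contains(np.nextafter(3.7, 0.0))
        assert not w.contains(np.nextafter(4.3, 5.0))

    def test_zero_sigma_degenerate_window_still_valid(self):
        w = sc.window_from_fret(4.0, 0.0, linker_offset=0.0)
        assert w.contains(4.0)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            sc.window_from_fret(4.0, -0.1)

    def test_window_swallowing_origin_rejected(self):
        with pytest.raises(ValueError, match="not positive"):
            sc.window_from_fret(0.5, 0.7, linker_offset=0.0)


class TestApplyWindow:
    WINDOW = sc.DistanceWindow(3.7, 4.3)

    def test_planted_in_window_count(self, planted_ensemble):
        ensemble, manifest = planted_ensemble
        distances = sc.measure_ensemble_dda(ensemble)
        retained = sc.apply_window(distances, self.WINDOW)
        assert len(retained) == manifest["n_in_window"] == 16
        planted = {p["model_id"] for p in manifest["poses"]
                   if p["cluster"] is not None}
        assert set(retained) == planted

    def test_preserves_input_order(self):
        distances = {"a": 4.0, "b": 1.0, "c": 3.8, "d": 4.2}
        assert sc.apply_window(distances, self.WINDOW) == ["a", "c", "d"]

    def test_idempotent(self, planted_ensemble):
        ensemble, _ = planted_ensemble
        distances = sc.measure_ensemble_dda(ensemble)
        once = sc.apply_window(distances, self.WINDOW)
        twice = sc.apply_window({m: distances[m] for m in once}, self.WINDOW)
        assert once == twice

    def test_monotone_in_window_width(self, planted_ensemble):
        ensemble, _ = planted_ensemble
        distances = sc.measure_ensemble_dda(ensemble)
        narrow = set(sc.apply_window(distances, sc.DistanceWindow(3.8, 4.2)))
        wide = set(sc.apply_window(distances, sc.DistanceWindow(3.7, 4.3)))
        assert narrow <= wide


class TestClustering:
    def test_planted_ensemble_forms_planted_clusters(self, planted_ensemble):
        ensemble, manifest = planted_ensemble
        distances = sc.measure_ensemble_dda(ensemble)
        retained = sc.apply_window(distances, sc.DistanceWindow(3.7, 4.3))
        clusters = sc.cluster_by_rmsd(ensemble, retained,
                                      threshold=manifest["rmsd_threshold_nm"])
        assert len(clusters.groups) == manifest["n_clusters"] == 5
        # recovered groups equal the planted partition
        planted = {}
        for p in manifest["poses"]:
            if p["cluster"] is not None:
                planted.setdefault(p["cluster"], set()).add(p["model_id"])
        recovered = {frozenset(g) for g in clusters.groups}
        assert recovered == {frozenset(v) for v in planted.values()}

    def test_group_sizes_match_plan(self, planted_ensemble):
        ensemble, manifest = planted_ensemble
        distances = sc.measure_ensemble_dda(ensemble)
        retained = sc.apply_window(distances, sc.DistanceWindow(3.7, 4.3))
        clusters = sc.cluster_by_rmsd(ensemble, retained, threshold=0.1)
        assert sorted(len(g) for g in clusters.groups) == [2, 2, 3, 4, 5]

    def test_representative_is_best_ranked_member(self, planted_ensemble):
        ensemble, _ = planted_ensemble
        distances = sc.measure_ensemble_dda(ensemble)
        retained = sc.apply_window(distances, sc.DistanceWindow(3.7, 4.3))
        clusters = sc.cluster_by_rmsd(ensemble, retained, threshold=0.1)
        for rep, grp in zip(clusters.representatives, clusters.groups):
            assert ensemble.rank_of(rep) == min(ensemble.rank_of(m) for m in grp)

    def test_identical_models_collapse_to_one_group(self, planted_ensemble):
        ensemble, _ = planted_ensemble
        some = [m.model_id for m in ensemble.models[:4]]
        base = ensemble.models[0]
        clones = sc.PoseEnsemble(models=[
            type(base)(mid, base.atoms, float(i)) for i, mid in enumerate(some)],
            sites=ensemble.sites)
        clusters = sc.cluster_by_rmsd(clones, some, threshold=0.1)
        assert len(clusters.groups) == 1
        assert set(clusters.groups[0]) == set(some)

    def test_tiny_threshold_gives_all_singletons(self, planted_ensemble):
        ensemble, _ = planted_ensemble
        distances = sc.measure_ensemble_dda(ensemble)
        retained = sc.apply_window(distances, sc.DistanceWindow(3.7, 4.3))
        clusters = sc.cluster_by_rmsd(ensemble, retained, threshold=1e-9)
        assert len(clusters.groups) == len(retained)

    def test_empty_retained_rejected(self, planted_ensemble):
        ensemble, _ = planted_ensemble
        with pytest.raises(ValueError):
            sc.cluster_by_rmsd(ensemble, [])


class TestRankByEnergy:
    def test_orders_by_ascending_energy(self):
        ordering, best = sc.rank_by_energy(
            ["a", "b", "c"], {"a": -10.0, "b": -30.0, "c": -20.0})
        assert ordering == ["b", "c", "a"]
        assert best == "b"

    def test_tie_broken_by_docking_rank(self, planted_ensemble):
        ensemble, _ = planted_ensemble
        ids = [m.model_id for m in ensemble.models[:3]]
        # give the worst-ranked two a tied best energy
        energies = {ids[0]: -5.0, ids[1]: -9.0, ids[2]: -9.0}
        ordering, best = sc.rank_by_energy([ids[2], ids[0], ids[1]],
                                           energies, ensemble)
        assert best == ids[1]
        assert ordering == [ids[1], ids[2], ids[0]]

    def test_missing_energy_is_an_error(self):
        with pytest.raises(ValueError, match="b"):
            sc.rank_by_energy(["a", "b"], {"a": -1.0})


class TestHistogram:
    def test_counts_sum_to_pose_count(self, planted_ensemble):
        ensemble, _ = planted_ensemble
        distances = sc.measure_ensemble_dda(ensemble)
        h = sc.distance_histogram(distances)
        assert sum(h["counts"]) == len(distances)

    def test_default_binning_layout(self):
        h = sc.distance_histogram({"x": 3.9})
        edges = h["bin_edges_nm"]
        assert edges[0] == 0.0 and edges[-1] == pytest.approx(7.0)
        assert len(edges) == 15 and len(h["counts"]) == 14
        assert h["counts"][7] == 1  # 3.9 falls in [3.5, 4.0)

    def test_known_distances_land_in_expected_bins(self):
        h = sc.distance_histogram({"a": 0.1, "b": 3.6, "c": 3.9, "d": 6.9})
        assert h["counts"][0] == 1
        assert h["counts"][7] == 2
        assert h["counts"][13] == 1


@pytest.fixture(scope="module")
def study_dir(tmp_path_factory):
    """A complete synthetic study on disk plus its pipeline config."""
    root = tmp_path_factory.mktemp("study")
    _, _, manifest = sd.gen_pose_ensemble(sd.PoseEnsembleSpec(), seed=20,
                                          out_dir=root)
    fio.write_titration_csv(
        sd.gen_titration(sd.TitrationSpec(noise_cv=0.0), seed=5),
        root / "titration.csv")
    decay_specs = {
        "free": sd.DecaySpec(amplitudes=(1.0, 0.0), lifetimes_ns=(2.79, 2.79),
                             poisson=False),
        "donor": sd.DecaySpec(amplitudes=(1.0, 0.0), lifetimes_ns=(2.82, 2.82),
                              poisson=False),
        "donor_acceptor": sd.DecaySpec(amplitudes=(1.0, 0.0),
                                       lifetimes_ns=(2.68, 2.68), poisson=False),
    }
    for key, spec in decay_specs.items():
        fio.write_decay_csv(sd.gen_decay(spec, seed=7), root / f"{key}.csv")
    config = {
        "titration": str(root / "titration.csv"),
        "decays": {k: str(root / f"{k}.csv") for k in decay_specs},
        "fret": {"r0": 2.5, "r0_sigma": 0.1,
                 "distance": {"R": 3.9, "sigma": 0.3}},
        "screening": {
            "poses_dir": str(root / "poses"),
            "scores_csv": str(root / "scores.csv"),
            "donor_chain": "A", "donor_residue": 146, "acceptor_chain": "B",
            "linker_offset": 0.1, "rmsd_threshold": 0.1,
        },
        "energies_csv": str(root / "energies.csv"),
        "output_dir": str(root / "out"),
    }
    return root, config, manifest


class TestPipeline:
    def test_recovers_planted_best_model(self, study_dir):
        _, config, manifest = study_dir
        report = sc.run_pipeline(config, seed=0)
        assert report.status == "ok"
        assert report.best_model == manifest["planted_best_model"]
        assert len(report.retained) == manifest["n_in_window"]
        assert len(report.clusters.groups) == manifest["n_clusters"]

    def test_quenching_and_lifetime_summary(self, study_dir):
        _, config, _ = study_dir
        report = sc.run_pipeline(config, seed=0)
        p = report.photophysics
        assert p["K_SV_per_M"] == pytest.approx(1.68e5, rel=1e-6)
        assert p["lifetimes_ns"]["tau_free"] == pytest.approx(2.79, rel=1e-3)
        assert p["lifetimes_ns"]["tau_D"] == pytest.approx(2.82, rel=1e-3)
        assert p["lifetimes_ns"]["tau_DA"] == pytest.approx(2.68, rel=1e-3)
        assert p["k_q_per_M_s"] == pytest.approx(6.02e13, rel=5e-3)
        assert p["quenching_mechanism"] == "static"

    def test_window_and_energy_ranking(self, study_dir):
        _, config, manifest = study_dir
        report = sc.run_pipeline(config, seed=0)
        assert report.window == pytest.approx((3.7, 4.3))
        best_dg = {p["model_id"]: p["dG_B"] for p in manifest["poses"]}
        energies = [report.energies[r] for r in report.ranking]
        assert energies == sorted(energies)
        assert report.energies[report.best_model] == pytest.approx(
            best_dg[manifest["planted_best_model"]])

    def test_deterministic_byte_identical_reports(self, study_dir):
        _, config, _ = study_dir
        r1 = sc.run_pipeline(config, seed=0).to_json()
        r2 = sc.run_pipeline(config, seed=0).to_json()
        assert r1 == r2

    def test_output_files_written_and_consistent(self, study_dir):
        root, config, _ = study_dir
        report = sc.run_pipeline(config, seed=0)
        out = root / "out"
        on_disk = json.loads((out / "report.json").read_text())
        assert on_disk == report.to_dict()
        lines = (out / "distances.tsv").read_text().strip().splitlines()
        assert len(lines) - 1 == len(report.distances)
        hist_lines = (out / "histogram.tsv").read_text().strip().splitlines()
        counts = [int(line.split("\t")[2]) for line in hist_lines[1:]]
        assert sum(counts) == len(report.distances)

    def test_empty_window_yields_empty_status(self, study_dir):
        _, config, _ = study_dir
        cfg = dict(config)
        cfg["fret"] = {"r0": 2.5, "r0_sigma": 0.1,
                       "distance": {"R": 25.0, "sigma": 0.1}}
        cfg.pop("output_dir", None)
        report = sc.run_pipeline(cfg, seed=0)
        assert report.status == "empty"
        assert report.retained == [] and report.best_model is None

    def test_lifetime_route_without_distance_override(self, study_dir):
        """The fitted 2.68/2.82 ns lifetimes alone still give a 4.1 nm window."""
        _, config, _ = study_dir
        cfg = dict(config)
        cfg["fret"] = {"r0": 2.5, "r0_sigma": 0.1}
        cfg.pop("output_dir", None)
        report = sc.run_pipeline(cfg, seed=0)
        R = report.fret["combined"]["R_nm"]
        sigma = report.fret["combined"]["R_sigma_nm"]
        assert R == pytest.approx(4.09, abs=0.01)
        assert sigma == pytest.approx(0.1 * R / 2.5, rel=1e-6)  # from R0 +/- 0.1
        lo, hi = report.window
        assert lo == pytest.approx(R - sigma + 0.1, rel=1e-9)
        assert hi == pytest.approx(R + sigma + 0.1, rel=1e-9)

    def test_score_csv_order_does_not_matter(self, study_dir, tmp_path):
        """Shuffling the score table's rows leaves the ranking unchanged."""
        root, config, _ = study_dir
        lines = (root / "scores.csv").read_text().strip().splitlines()
        header, rows = lines[0], lines[1:]
        shuffled = tmp_path / "scores_shuffled.csv"
        shuffled.write_text("\n".join([header] + rows[::-1]) + "\n")
        cfg = dict(config)
        cfg["screening"] = dict(config["screening"],
                                scores_csv=str(shuffled))
        cfg.pop("output_dir", None)
        base = sc.run_pipeline(config, seed=0)
        alt = sc.run_pipeline(cfg, seed=0)
        assert alt.ranking == base.ranking and alt.best_model == base.best_model

    def test_missing_fret_section_is_an_error(self, study_dir):
        _, config, _ = study_dir
        cfg = {k: v for k, v in config.items()
               if k not in ("fret", "decays", "output_dir")}
        with pytest.raises(RuntimeError, match="FRET stage"):
            sc.run_pipeline(cfg, seed=0)

    def test_yaml_config_file_accepted(self, study_dir, tmp_path):
        import yaml
        _, config, manifest = study_dir
        cfg = dict(config)
        cfg.pop("output_dir", None)
        path = tmp_path / "config.yaml"
        path.write_text(yaml.safe_dump(cfg))
        report = sc.run_pipeline(path, seed=0)
        assert report.best_model == manifest["planted_best_model"]
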