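"""FRET-restrained screening of docked pose ensembles.

The selection procedure this module implements:

1. measure the donor-acceptor distance D_DA in every docked model;
2. build a retention window from the FRET-derived distance
   (R ± sigma, widened by the dye-linker offset) and discard models whose
   D_DA falls outside it;
3. group the survivors by pairwise RMSD (models closer than a threshold
   belong together), taking the best docking-ranked member of each group
   as its representative;
4. rank the representatives by binding free energy and select the lowest
   dG_B as the best model.

``run_pipeline`` orchestrates the whole analysis — quenching constants,
FRET distances from up to three methods, window filtering, clustering and
energy ranking — from a single configuration mapping, deterministically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import fret as fret_mod
from . import photophysics as photo
from .energetics import BindingComponents, read_component_table
from .structure import SitePair, StructureModel, dda_distance, read_pdb, rmsd

logger = logging.getLogger(__name__)

__all__ = [
    "PoseEnsemble",
    "DistanceWindow",
    "ClusterSet",
    "ScreeningReport",
    "measure_ensemble_dda",
    "window_from_fret",
    "apply_window",
    "cluster_by_rmsd",
    "rank_by_energy",
    "distance_histogram",
    "run_pipeline",
    "load_pose_directory",
]


@dataclass
class PoseEnsemble:
    """Docked models in docking-rank order (best score first) plus site locators."""

    models: list[StructureModel]
    sites: SitePair

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("an ensemble needs at least one model")
        ids = [m.model_id for m in self.models]
        if len(set(ids)) != len(ids):
            raise ValueError("model ids must be unique")

    def rank_of(self, model_id: str) -> int:
        for i, m in enumerate(self.models):
            if m.model_id == model_id:
                return i
        raise KeyError(model_id)


@dataclass(frozen=True)
class DistanceWindow:
    """Closed retention interval [low, high] for D_DA, in nm."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError("need 0 < low < high")

    def contains(self, value: float) -> bool:
        return self.low <= value <= self.high


@dataclass(frozen=True)
class ClusterSet:
    """A partition of retained models into RMSD groups with representatives."""

    groups: tuple          # tuple of tuples of model ids
    representatives: tuple # one id per group, best docking rank in the group

    def __post_init__(self) -> None:
        flat = [mid for g in self.groups for mid in g]
        if len(set(flat)) != len(flat):
            raise ValueError("groups must be disjoint")
        if len(self.representatives) != len(self.groups):
            raise ValueError("one representative per group required")
        for rep, grp in zip(self.representatives, self.groups):
            if rep not in grp:
                raise ValueError(f"representative {rep} not in its group")


@dataclass
class ScreeningReport:
    """Everything the screening produced, JSON-serialisable."""

    distances: dict               # model_id -> D_DA (nm)
    window: tuple                 # (low, high) nm
    retained: list                # model ids, rank order
    clusters: ClusterSet | None
    energies: dict                # representative id -> dG_B (kJ/mol)
    ranking: list                 # representative ids, ascending dG_B
    best_model: str | None
    histogram: dict               # {"bin_edges_nm": [...], "counts": [...]}
    photophysics: dict = field(default_factory=dict)
    fret: dict = field(default_factory=dict)
    status: str = "ok"

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "photophysics": self.photophysics,
            "fret": self.fret,
            "distances_nm": self.distances,
            "window_nm": list(self.window),
            "retained": self.retained,
            "clusters": None if self.clusters is None else {
                "groups": [list(g) for g in self.clusters.groups],
                "representatives": list(self.clusters.representatives),
            },
            "dG_B_kJ_per_mol": self.energies,
            "ranking": self.ranking,
            "best_model": self.best_model,
            "histogram": self.histogram,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 1)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


# ---------------------------------------------------------------------------
# individual screening steps
# ---------------------------------------------------------------------------

def measure_ensemble_dda(ensemble: PoseEnsemble) -> dict[str, float]:
    """D_DA (nm) for every model, in docking-rank order.

    Any model whose donor or acceptor anchor cannot be resolved aborts the
    measurement with an error naming that model.
    """
    out: dict[str, float] = {}
    for model in ensemble.models:
        try:
            out[model.model_id] = dda_distance(model, ensemble.sites)
        except ValueError as exc:
            raise ValueError(f"model {model.model_id}: {exc}") from exc
    return out


def window_from_fret(R: float, R_sigma: float, linker_offset: float = 0.1
                     ) -> DistanceWindow:
    """Retention window [R - sigma + linker, R + sigma + linker].

    The dye sits one linker length beyond the geometric 5' anchor, so the
    window on the *geometric* D_DA is the experimental interval shifted by
    ``linker_offset``.
    """
    if R_sigma < 0:
        raise ValueError("R_sigma must be non-negative")
    low = R - R_sigma + linker_offset
    high = R + R_sigma + linker_offset
    if low <= 0:
        raise ValueError(f"window lower bound {low:g} nm is not positive")
    if low == high:
        # degenerate but legal window; widen infinitesimally for the type invariant
        return DistanceWindow(low, np.nextafter(high, np.inf))
    return DistanceWindow(low, high)


def apply_window(distances: Mapping[str, float], window: DistanceWindow) -> list[str]:
    """Model ids whose D_DA lies inside the closed window, original order kept."""
    return [mid for mid, d in distances.items() if window.contains(d)]


def cluster_by_rmsd(ensemble: PoseEnsemble, retained: Sequence[str],
                    threshold: float = 0.1, selection: str | None = None,
                    fit: bool = False) -> ClusterSet:
    """Greedy leader clustering of retained models in docking-rank order.

    Walking the retained models from best docking rank down, each model
    joins the first existing group whose representative (leader) is within
    ``threshold`` nm RMSD, otherwise it founds a new group. Representatives
    are therefore always the best-ranked member of their group.
    """
    if not retained:
        raise ValueError("no retained models to cluster")
    by_id = {m.model_id: m for m in ensemble.models}
    ordered = [m.model_id for m in ensemble.models if m.model_id in set(retained)]

    leaders: list[str] = []
    groups: list[list[str]] = []
    for mid in ordered:
        for gi, leader in enumerate(leaders):
            if rmsd(by_id[mid], by_id[leader], selection=selection, fit=fit) < threshold:
                groups[gi].append(mid)
                break
        else:
            leaders.append(mid)
            groups.append([mid])
    return ClusterSet(groups=tuple(tuple(g) for g in groups),
                      representatives=tuple(leaders))


def rank_by_energy(representatives: Sequence[str], energies: Mapping[str, float],
                   ensemble: PoseEnsemble | None = None
                   ) -> tuple[list[str], str]:
    """Order representatives by ascending dG_B; return (ordering, best).

    Ties are broken by docking rank when an ensemble is supplied, otherwise
    by input order.
    """
    missing = [r for r in representatives if r not in energies]
    if missing:
        raise ValueError(f"no binding energy for representative(s) {missing}")
    if ensemble is not None:
        tiebreak = {r: ensemble.rank_of(r) for r in representatives}
    else:
        tiebreak = {r: i for i, r in enumerate(representatives)}
    ordering = sorted(representatives, key=lambda r: (energies[r], tiebreak[r]))
    return ordering, ordering[0]


def distance_histogram(distances: Mapping[str, float], bin_width: float = 0.5,
                       range_nm: tuple = (0.0, 7.0)) -> dict:
    """Histogram of D_DA values (default 0.5 nm bins over [0, 7] nm)."""
    edges = np.arange(range_nm[0], range_nm[1] + bin_width / 2, bin_width)
    counts, _ = np.histogram(list(distances.values()), bins=edges)
    return {"bin_edges_nm": edges.tolist(), "counts": counts.tolist()}


def load_pose_directory(pose_dir: str | Path, scores: Mapping[str, float],
                        sites: SitePair) -> PoseEnsemble:
    """Read every ``*.pdb`` in a directory and order models by docking score.

    Rank comes from the scores table, never from file-listing order, so the
    result is invariant under directory enumeration order.
    """
    pose_dir = Path(pose_dir)
    paths = sorted(pose_dir.glob("*.pdb"))
    if not paths:
        raise ValueError(f"no PDB files in {pose_dir}")
    models = []
    for p in paths:
        mid = p.stem
        if mid not in scores:
            raise ValueError(f"no docking score for model {mid!r}")
        models.append(read_pdb(p, model_id=mid, docking_score=float(scores[mid])))
    models.sort(key=lambda m: (m.docking_score, m.model_id))
    return PoseEnsemble(models=models, sites=sites)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def _fret_distances(cfg: Mapping, photo_summary: dict) -> tuple[list, dict]:
    """Distance estimates from whichever efficiency routes the config provides."""
    pair = fret_mod.ForsterPair(
        R0=float(cfg.get("r0", 2.5)), R0_sigma=float(cfg.get("r0_sigma", 0.1)),
        epsilon_donor=cfg.get("eps_D"), epsilon_acceptor=cfg.get("eps_A"),
    )
    estimates = []
    detail = {"R0_nm": pair.R0, "R0_sigma_nm": pair.R0_sigma, "methods": {}}

    dq = cfg.get("donor_quench")
    if dq:
        est = fret_mod.efficiency_donor_quench(float(dq["F_D"]), float(dq["F_DA"]))
        est = fret_mod.EfficiencyEstimate(est.E, float(dq.get("E_sigma", 0.0)), est.method)
        dist = fret_mod.distance_from_efficiency(est, pair)
        estimates.append(dist)
        detail["methods"]["donor_quench"] = {"E": est.E, "R_nm": dist.R,
                                             "R_sigma_nm": dist.R_sigma}
    acc = cfg.get("acceptor")
    if acc:
        acc_pair = fret_mod.ForsterPair(
            R0=pair.R0, R0_sigma=pair.R0_sigma,
            epsilon_donor=float(acc.get("eps_D", cfg.get("eps_D", 1500.0))),
            epsilon_acceptor=float(acc.get("eps_A", cfg.get("eps_A", 2700.0))),
        )
        est = fret_mod.efficiency_acceptor_enhance(
            float(acc["F_A"]), float(acc["F_AD"]), acc_pair)
        est = fret_mod.EfficiencyEstimate(est.E, float(acc.get("E_sigma", 0.0)), est.method)
        dist = fret_mod.distance_from_efficiency(est, acc_pair)
        estimates.append(dist)
        detail["methods"]["acceptor_enhance"] = {"E": est.E, "R_nm": dist.R,
                                                 "R_sigma_nm": dist.R_sigma}
    lt = cfg.get("lifetimes")
    if lt:
        est = fret_mod.efficiency_from_lifetimes(float(lt["tau_DA"]), float(lt["tau_D"]))
        est = fret_mod.EfficiencyEstimate(est.E, float(lt.get("E_sigma", 0.0)), est.method)
        dist = fret_mod.distance_from_efficiency(est, pair)
        estimates.append(dist)
        detail["methods"]["lifetime"] = {"E": est.E, "R_nm": dist.R,
                                         "R_sigma_nm": dist.R_sigma}

    if cfg.get("distance"):
        d = cfg["distance"]
        combined = fret_mod.DistanceEstimate(float(d["R"]), float(d.get("sigma", 0.0)),
                                             "combined")
    elif estimates:
        combined = fret_mod.combine_distances(estimates)
    else:
        raise ValueError("fret config provides no efficiency route and no distance")
    detail["combined"] = {"R_nm": combined.R, "R_sigma_nm": combined.R_sigma}
    return [combined], detail


def run_pipeline(config: Mapping | str | Path, seed: int | None = None) -> ScreeningReport:
    """Run quenching → FRET → window → filter → cluster → energy ranking.

    ``config`` is a mapping (or a path to a YAML file) with the sections:

    * ``titration`` (optional): path to a conc_M,intensity CSV; yields K_SV,
      k_q (using the donor lifetime) and the quenching classification.
    * ``decays`` (optional): ``{donor: path, donor_acceptor: path}`` TCSPC
      CSVs; fitted lifetimes feed the lifetime FRET method.
    * ``fret``: r0 / r0_sigma, plus any of ``donor_quench`` {F_D, F_DA},
      ``acceptor`` {F_A, F_AD, eps_A, eps_D}, ``lifetimes`` {tau_D, tau_DA}
      (ns), or a direct ``distance`` {R, sigma} override.
    * ``screening``: ``poses_dir``, ``scores_csv``, site locators
      (``donor_chain``, ``donor_residue``, ``acceptor_chain``),
      ``linker_offset`` (nm, default 0.1), ``rmsd_threshold`` (nm, default
      0.1), optional ``rmsd_fit`` / ``rmsd_selection``.
    * ``energies_csv``: per-binding component ledger with dG_B per model.
    * ``seed`` (overridden by the ``seed`` argument when given).
    * ``output_dir`` (optional): where to write report.json,
      distances.tsv and histogram.tsv.

    An empty retained set yields a report with ``status='empty'`` rather
    than an error. The result is fully deterministic given (config, seed).
    """
    import yaml

    if not isinstance(config, Mapping):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    seed = int(config.get("seed", 0)) if seed is None else int(seed)

    photo_summary: dict = {}
    fret_cfg = dict(config.get("fret", {}))

    # stage: time-resolved photophysics (optional)
    try:
        decays = config.get("decays") or {}
        taus: dict[str, float] = {}
        from .io import read_decay_csv
        # "free": unquenched donor (protein alone); "donor": donor in the
        # complex without acceptor; "donor_acceptor": donor with acceptor
        for key, label in (("free", "tau_free"), ("donor", "tau_D"),
                           ("donor_acceptor", "tau_DA")):
            if key in decays:
                fit = photo.fit_biexponential(read_decay_csv(decays[key]), seed=seed)
                taus[label] = photo.mean_lifetime(fit)
        if taus:
            photo_summary["lifetimes_ns"] = taus
            if "tau_D" in taus and "tau_DA" in taus and "lifetimes" not in fret_cfg:
                fret_cfg["lifetimes"] = {"tau_D": taus["tau_D"],
                                         "tau_DA": taus["tau_DA"]}
    except Exception as exc:
        raise RuntimeError(f"lifetime stage failed: {exc}") from exc

    # stage: steady-state quenching (optional)
    try:
        if config.get("titration"):
            from .io import read_titration_csv
            sv = photo.stern_volmer_fit(read_titration_csv(config["titration"]))
            photo_summary["K_SV_per_M"] = sv.K_SV
            photo_summary["K_SV_sigma_per_M"] = sv.K_SV_sigma
            photo_summary["sv_intercept"] = sv.intercept
            photo_summary["sv_r_squared"] = sv.r_squared
            # k_q uses the unquenched donor lifetime; the mechanism check
            # compares it with the lifetime in the presence of the quencher
            taus_known = photo_summary.get("lifetimes_ns", {})
            tau_free = taus_known.get("tau_free", taus_known.get("tau_D"))
            if tau_free is None and fret_cfg.get("lifetimes"):
                tau_free = float(fret_cfg["lifetimes"]["tau_D"])
            if tau_free:
                k_q = photo.bimolecular_quenching_constant(sv.K_SV, tau_free * 1e-9)
                photo_summary["k_q_per_M_s"] = k_q
                tau_quenched = taus_known.get("tau_D")
                if "tau_free" in taus_known and tau_quenched is not None:
                    photo_summary["quenching_mechanism"] = photo.classify_quenching(
                        k_q, tau_free, float(tau_quenched))
    except Exception as exc:
        raise RuntimeError(f"quenching stage failed: {exc}") from exc

    # stage: FRET distances
    try:
        estimates, fret_detail = _fret_distances(fret_cfg, photo_summary)
        combined = estimates[0]
    except Exception as exc:
        raise RuntimeError(f"FRET stage failed: {exc}") from exc

    # stage: structures and window filtering
    scr = config.get("screening", {})
    try:
        sites = SitePair(
            donor_chain=str(scr.get("donor_chain", "A")),
            donor_residue=int(scr.get("donor_residue", 146)),
            acceptor_chain=str(scr.get("acceptor_chain", "B")),
            linker_offset=float(scr.get("linker_offset", 0.1)),
        )
        from .io import read_scores_csv
        scores = read_scores_csv(scr["scores_csv"])
        ensemble = load_pose_directory(scr["poses_dir"], scores, sites)
        distances = measure_ensemble_dda(ensemble)
        window = window_from_fret(combined.R, combined.R_sigma, sites.linker_offset)
        retained = apply_window(distances, window)
        histogram = distance_histogram(distances)
    except Exception as exc:
        raise RuntimeError(f"screening stage failed: {exc}") from exc

    if not retained:
        report = ScreeningReport(
            distances=distances, window=(window.low, window.high), retained=[],
            clusters=None, energies={}, ranking=[], best_model=None,
            histogram=histogram, photophysics=photo_summary, fret=fret_detail,
            status="empty",
        )
        _write_outputs(config, report)
        return report

    # stage: clustering and energy ranking
    try:
        clusters = cluster_by_rmsd(
            ensemble, retained, threshold=float(scr.get("rmsd_threshold", 0.1)),
            selection=scr.get("rmsd_selection"), fit=bool(scr.get("rmsd_fit", False)))
        components = read_component_table(config["energies_csv"])
        if components and isinstance(components[0], BindingComponents):
            energy_map = {c.model_id: c.dG_B for c in components}
        else:
            raise ValueError("energies_csv must be a per-binding (delta) ledger")
        reps = list(clusters.representatives)
        rep_energies = {r: energy_map[r] for r in reps if r in energy_map}
        ranking, best = rank_by_energy(reps, rep_energies, ensemble)
    except Exception as exc:
        raise RuntimeError(f"ranking stage failed: {exc}") from exc

    report = ScreeningReport(
        distances=distances, window=(window.low, window.high), retained=retained,
        clusters=clusters, energies=rep_energies, ranking=ranking,
        best_model=best, histogram=histogram, photophysics=photo_summary,
        fret=fret_detail,
    )
    _write_outputs(config, report)
    return report


def _write_outputs(config: Mapping, report: ScreeningReport) -> None:
    out_dir = config.get("output_dir")
    if not out_dir:
        return
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json() + "\n")
    with (out / "distances.tsv").open("w") as fh:
        fh.write("model_id\tD_DA_nm\n")
        for mid, d in report.distances.items():
            fh.write(f"{mid}\t{d:.6f}\n")
    with (out / "histogram.tsv").open("w") as fh:
        fh.write("bin_low_nm\tbin_high_nm\tcount\n")
        edges = report.histogram["bin_edges_nm"]
        for lo, hi, c in zip(edges[:-1], edges[1:], report.histogram["counts"]):
            fh.write(f"{lo:.2f}\t{hi:.2f}\t{c}\n")
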