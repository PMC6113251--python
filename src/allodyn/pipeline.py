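"""Workflow orchestration: align → observables → correlation → PCA → network
→ communities → (optional) energetics, over one or two conditions.

A run is described by a YAML config (validated up front, with every
violation reported at once), executed stage by stage with a JSON manifest
recording inputs, parameters, package version and seed for each output.
All numeric output formatting is deterministic, so a rerun with the same
config and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import corr_pca, energetics, metrics, network, synthetic, trajio

logger = logging.getLogger(__name__)

WINDOW_SHORTCUTS = {
    "all": 1.0,
    "last-half": 0.5,
    "last-quarter": 0.25,
    "last-eighth": 0.125,
    "last-sixteenth": 0.0625,
}


class ConfigError(ValueError):
    """Carries the complete list of config violations, not just the first."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid config:\n  - " + "\n  - ".join(violations))


@dataclass
class ConditionInput:
    label: str
    structure_path: str | None = None
    trajectory_path: str | None = None
    synthetic_spec: synthetic.SyntheticSpec | None = None


@dataclass
class RunConfig:
    output_dir: str
    seed: int = 0
    conditions: list[ConditionInput] = field(default_factory=list)
    node_selection: str = "name CA"
    align_selection: str = "name CA"
    window: object = "all"  # [a, b] in frames or a named trailing fraction
    contact_cutoff: float = 4.5
    occupancy_threshold: float = 0.75
    pca_components: int = 2
    energetics_mode: str = "none"  # none | computed | table
    receptor_selection: str | None = None
    ligand_selection: str | None = None
    energy_tables: dict | None = None
    entropy: bool = False
    distances: list = field(default_factory=list)
    sasa_selection: str | None = None
    sasa_reference: float | None = None


def resolve_window(window, n_frames: int) -> tuple[int, int]:
    """Frame window from an explicit [a, b) pair or a trailing-fraction name."""
    if isinstance(window, str):
        if window not in WINDOW_SHORTCUTS:
            raise ValueError(f"unknown window shortcut {window!r}")
        frac = WINDOW_SHORTCUTS[window]
        start = n_frames - max(2, int(round(frac * n_frames)))
        return (max(0, start), n_frames)
    a, b = int(window[0]), int(window[1])
    if not (0 <= a < b <= n_frames):
        raise ValueError(f"window [{a}, {b}) outside trajectory of {n_frames} frames")
    return (a, b)


def _parse_synthetic_spec(d: dict, seed: int) -> synthetic.SyntheticSpec:
    blocks = [
        synthetic.CovarianceBlock(
            members=list(b["members"]),
            within=float(b["within"]),
            amplitude=float(b.get("amplitude", 0.5)),
        )
        for b in d.get("blocks", [])
    ]
    contacts = [
        synthetic.ContactPlan(
            res_i=int(c["res_i"]),
            res_j=int(c["res_j"]),
            occupancy=float(c["occupancy"]),
            contact_distance=float(c.get("contact_distance", 4.0)),
            noncontact_distance=float(c.get("noncontact_distance", 9.0)),
        )
        for c in d.get("contacts", [])
    ]
    return synthetic.SyntheticSpec(
        chain_sizes={str(k): int(v) for k, v in d["chains"].items()},
        n_frames=int(d.get("n_frames", 1000)),
        seed=int(d.get("seed", seed)),
        blocks=blocks,
        between=float(d.get("between", 0.0)),
        default_amplitude=float(d.get("default_amplitude", 0.3)),
        contacts=contacts,
        geometry=str(d.get("geometry", "helix")),
    )


def validate_config(path) -> RunConfig:
    """Parse and validate a YAML run config; report every violation at once."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(["config root must be a mapping"])
    violations: list[str] = []

    out_dir = raw.get("output_dir")
    if not out_dir:
        violations.append("output_dir is required")
    seed = int(raw.get("seed", 0))

    conditions: list[ConditionInput] = []
    raw_conditions = raw.get("conditions", [])
    if not raw_conditions:
        violations.append("at least one condition is required")
    for i, c in enumerate(raw_conditions):
        label = c.get("label", f"condition{i}")
        if "synthetic" in c:
            try:
                spec = _parse_synthetic_spec(c["synthetic"], seed)
                conditions.append(ConditionInput(label=label, synthetic_spec=spec))
            except (KeyError, TypeError, ValueError) as exc:
                violations.append(f"condition {label!r}: bad synthetic spec ({exc})")
        else:
            sp, tp = c.get("structure"), c.get("trajectory")
            for name, p in (("structure", sp), ("trajectory", tp)):
                if p is None:
                    violations.append(f"condition {label!r}: {name} path missing")
                elif not Path(p).exists():
                    violations.append(f"condition {label!r}: {name} file {p!r} not found")
            conditions.append(
                ConditionInput(label=label, structure_path=sp, trajectory_path=tp)
            )

    thr = float(raw.get("occupancy_threshold", 0.75))
    if not (0.0 <= thr <= 1.0):
        violations.append(f"occupancy_threshold {thr} must be in [0,1]")
    cutoff = float(raw.get("contact_cutoff", 4.5))
    if cutoff <= 0:
        violations.append(f"contact_cutoff {cutoff} must be positive")
    k = int(raw.get("pca_components", 2))
    if k < 1:
        violations.append(f"pca_components {k} must be >= 1")
    window = raw.get("window", "all")
    if isinstance(window, str) and window not in WINDOW_SHORTCUTS:
        violations.append(
            f"window shortcut {window!r} unknown (choose from {sorted(WINDOW_SHORTCUTS)})"
        )
    if isinstance(window, (list, tuple)) and (
        len(window) != 2 or int(window[0]) >= int(window[1]) or int(window[0]) < 0
    ):
        violations.append(f"window {window} must be [start, end) with 0 <= start < end")

    emode = raw.get("energetics", {}).get("mode", "none") if isinstance(
        raw.get("energetics"), dict
    ) else "none"
    e = raw.get("energetics") or {}
    if emode not in ("none", "computed", "table"):
        violations.append(f"energetics mode {emode!r} unknown")
    if emode in ("computed", "table"):
        for key in ("receptor", "ligand"):
            if not e.get(key):
                violations.append(f"energetics mode {emode!r} needs a {key} selection")
    if emode == "table":
        tabs = e.get("tables", {})
        for key in ("complex", "receptor", "ligand"):
            if key not in tabs:
                violations.append(f"energetics table mode needs a {key!r} table path")
            elif not Path(tabs[key]).exists():
                violations.append(f"energetics table {tabs[key]!r} not found")

    if violations:
        raise ConfigError(violations)
    return RunConfig(
        output_dir=str(out_dir),
        seed=seed,
        conditions=conditions,
        node_selection=str(raw.get("node_selection", "name CA")),
        align_selection=str(raw.get("align_selection", "name CA")),
        window=window,
        contact_cutoff=cutoff,
        occupancy_threshold=thr,
        pca_components=k,
        energetics_mode=emode,
        receptor_selection=e.get("receptor"),
        ligand_selection=e.get("ligand"),
        energy_tables=e.get("tables"),
        entropy=bool(raw.get("entropy", False)),
        distances=raw.get("distances", []),
        sasa_selection=raw.get("sasa_selection"),
        sasa_reference=raw.get("sasa_reference"),
    )


def _load_condition(cond: ConditionInput, outdir: Path):
    if cond.synthetic_spec is not None:
        traj, truth = synthetic.generate_trajectory(cond.synthetic_spec)
        trajio.write_pdb(traj.structure, outdir / "synthetic_reference.pdb")
        trajio.write_trajectory(traj, outdir / "synthetic_trajectory.dcd")
        synthetic.write_ground_truth(truth, outdir / "ground_truth.txt")
        return traj
    structure = trajio.read_pdb(cond.structure_path)
    return trajio.read_trajectory(structure, cond.trajectory_path)


def _run_condition(config: RunConfig, cond: ConditionInput) -> dict:
    outdir = Path(config.output_dir) / cond.label
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "label": cond.label,
        "package_version": __version__,
        "seed": config.seed,
        "stages": [],
    }

    def record(stage: str, outputs: list[str], **params):
        manifest["stages"].append(
            {"stage": stage, "outputs": outputs, "parameters": params}
        )

    traj = _load_condition(cond, outdir)
    window = resolve_window(config.window, traj.n_frames)
    sel = trajio.select(traj.structure, config.node_selection)
    align_sel = trajio.select(traj.structure, config.align_selection)

    aligned = trajio.align_trajectory(traj, align_sel, reference="average-iterative")
    record("align", [], selection=config.align_selection, reference="average-iterative")

    profiles = metrics.rmsf(aligned, sel, window)
    metrics.write_profile(
        outdir / "rmsf.txt",
        [p.residue_index for p in profiles],
        [p.value for p in profiles],
        header="residue rmsf_A",
    )
    record("rmsf", ["rmsf.txt"], window=list(window), selection=config.node_selection)

    for k, d in enumerate(config.distances):
        series = metrics.distance_series(
            traj, d["i"], d["j"], mode=d.get("mode", "atom-atom"), window=window
        )
        metrics.write_profile(
            outdir / f"distance_{k}.txt",
            range(window[0], window[1]),
            series.values,
            header=f"frame distance_A ({d['i']} vs {d['j']})",
        )
        record("distance", [f"distance_{k}.txt"], **d)

    if config.sasa_selection:
        ssel = trajio.select(traj.structure, config.sasa_selection)
        values, exceed = metrics.sasa_series(
            traj, ssel, window, reference_value=config.sasa_reference
        )
        metrics.write_profile(
            outdir / "sasa.txt",
            range(window[0], window[1]),
            values,
            header="frame sasa_A2",
        )
        record(
            "sasa",
            ["sasa.txt"],
            selection=config.sasa_selection,
            exceedance_fraction=exceed,
        )

    cm = corr_pca.cross_correlation(aligned, sel, window)
    corr_pca.write_correlation_matrix(cm, outdir / "correlation.txt")
    record("correlation", ["correlation.txt"], window=list(window))

    pca_res = corr_pca.pca(aligned, sel, window, n_components=config.pca_components)
    corr_pca.write_pca(pca_res, outdir / "pca_eigen.txt", outdir / "pca_proj.txt")
    record("pca", ["pca_eigen.txt", "pca_proj.txt"], n_components=config.pca_components)

    occ = network.contact_occupancy(traj, sel, config.contact_cutoff, window)
    net = network.build_network(occ, cm, config.occupancy_threshold)
    network.write_edge_list(net, outdir / "edges.txt")
    record(
        "network",
        ["edges.txt"],
        cutoff=config.contact_cutoff,
        occupancy_threshold=config.occupancy_threshold,
    )

    partition = network.girvan_newman(net)
    network.write_partition(partition, net.nodes, outdir / "communities.txt")
    network.write_gml(net, partition, outdir / "network.gml")
    chain_map = {pos: net.chain_of[res] for pos, res in enumerate(net.nodes)}
    iface = network.interface_communities(partition, chain_map)
    record("communities", ["communities.txt", "network.gml"])

    paths = network.shortest_paths(net)
    record("paths", [], cpl=paths.cpl, unreachable_pairs=paths.n_unreachable_pairs)

    summary = {
        "label": cond.label,
        "n_frames": traj.n_frames,
        "window": list(window),
        "n_nodes": len(net.nodes),
        "n_edges": net.graph.number_of_edges(),
        "cpl": paths.cpl,
        "n_communities": partition.n_communities,
        "modularity": partition.modularity,
        "interface_communities": iface,
        "n_interface_communities": len(iface),
        "pc1_information": float(pca_res.information[0]),
        "pc2_information": float(pca_res.information[1])
        if len(pca_res.information) > 1
        else 0.0,
        "mean_rmsf": float(np.mean([p.value for p in profiles])),
    }

    if config.energetics_mode != "none":
        comp_sel = trajio.select(traj.structure, "all")
        rec_sel = trajio.select(traj.structure, config.receptor_selection)
        lig_sel = trajio.select(traj.structure, config.ligand_selection)
        if config.energetics_mode == "table":
            tables = {
                k: energetics.read_term_table(v)
                for k, v in config.energy_tables.items()
            }
            decomp = energetics.decompose_single_trajectory(
                traj, comp_sel, rec_sel, lig_sel, window,
                term_source="table", tables=tables,
            )
        else:
            decomp = energetics.decompose_single_trajectory(
                traj, comp_sel, rec_sel, lig_sel, window, term_source="computed"
            )
        bfe = energetics.binding_free_energy(decomp)
        (outdir / "gbsa_summary.txt").write_text(energetics.format_summary(bfe) + "\n")
        record("gbsa", ["gbsa_summary.txt"], mode=config.energetics_mode)
        summary["dG_bind"] = bfe.dG_bind
        summary["dG_bind_std"] = bfe.dG_bind_std

    if config.entropy:
        ent = energetics.quasiharmonic_entropy(aligned, sel, window)
        summary["TS_conf"] = ent.TS
        record("entropy", [], temperature=ent.temperature, n_excluded=ent.n_excluded)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return summary


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage for each condition; write a comparison report.

    Returns the report dict (also written to ``<output_dir>/report.json``).
    A stage failure aborts with the stage named in the raised error; outputs
    of completed stages are retained on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summaries = []
    for cond in config.conditions:
        logger.info("running condition %s", cond.label)
        try:
            summaries.append(_run_condition(config, cond))
        except Exception as exc:
            raise RuntimeError(f"condition {cond.label!r} failed: {exc}") from exc

    report: dict = {"conditions": summaries, "seed": config.seed}
    if len(summaries) == 2:
        a, b = summaries
        deltas = {}
        for key in ("cpl", "n_communities", "n_interface_communities",
                    "pc1_information", "mean_rmsf", "dG_bind"):
            if key in a and key in b:
                deltas[key] = b[key] - a[key]
        report["comparison"] = {
            "labels": [a["label"], b["label"]],
            "deltas": deltas,
        }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
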