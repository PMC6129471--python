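"""End-to-end docking pipeline: fixtures → grids → docking → clustering →
classification → H-bonds → report.

One flat config (YAML sections per stage) drives every stage; unset keys
fall back to the protocol defaults (1 ps timestep, 185/204 Å start/stop,
98/40 Å encounter criteria, 1 Å deduplication, 5000-record archive, 10
clusters, 20000 trajectories, 3.2–3.6 Å H-bond window, 0.5 Å excluded
volume, 298.15 K, 100 mM, ε = 78.54/2).  The master seed is mandatory for
stochastic stages; per-(variant, conformer) engine seeds are derived from
it, so a rerun with the same config reproduces every artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bd import DockingField, RecordedSet, SimulationConfig, run_docking
from .classify import build_match_matrix, classify
from .cluster import cluster_recorded_set
from .electrostatics import (
    EffectiveChargeSet,
    build_exclusion_grid,
    debye_huckel_grid,
    read_dx_grid,
    write_dx_grid,
)
from .hbonds import aggregate_hbonds, find_hbonds
from .synthetic import (
    FixtureSpec,
    build_ideal_nucleosome,
    build_toy_lh,
    load_fixture_files,
    write_fixture_files,
)
from .variants import apply_variant

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline", "STAGES"]

DEFAULT_CONFIG: dict = {
    "seed": None,  # master seed; mandatory for the docking stage
    "fixture": {
        "core_bp": 147,
        "l_dna_bp": 10,
        "lh_size": 80,
        "lh_net_charge": 11,
    },
    "conformers": [[0.0, 0.0]],  # L-DNA opening-angle pairs (deg)
    "grid": {
        "spacing": 1.0,  # Å
        "padding": None,  # Å; three Debye lengths when unset
        "temperature": 298.15,  # K
        "ionic_strength": 0.100,  # mol/L
        "eps_solvent": 78.54,
        "eps_solute": 2.0,
    },
    "exclusion": {"margin": 0.5, "spacing": 0.5},
    "docking": {
        "timestep": 1.0,
        "start_radius": 185.0,
        "stop_radius": 204.0,
        "n_trajectories": 20000,
        "encounter_c2c_max": 98.0,
        "encounter_dyad_max": 40.0,
        "dedup_rmsd": 1.0,
        "capacity": 5000,
        "max_steps": 100_000_000,
        "max_displacement": 10.0,
        "max_retries": 50,
        "auto_scale": False,
        "D_trans": None,
        "D_rot": None,
    },
    "clustering": {"n_clusters": 10, "top_n": 2},
    "classification": {"contact_cutoff": 5.0, "helical_repeat": 10.4,
                       "theta_x": 30.0},
    "hbonds": {"d_min": 3.2, "d_max": 3.6, "enforce_lower_bound": True},
    "variants": [],
}


def validate_config(config: dict | str | Path | None) -> dict:
    """Normalize a config mapping (or YAML path), filling all defaults.

    Unknown keys raise (naming the key); contradictory values are listed
    together in one error.
    """
    if config is None:
        config = {}
    if isinstance(config, (str, Path)):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    out = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in config.items():
        if key not in out:
            raise ValueError(f"unknown config key {key!r}")
        if isinstance(out[key], dict):
            if not isinstance(val, dict):
                raise ValueError(f"config section {key!r} must be a mapping")
            for sub, sval in val.items():
                if sub not in out[key]:
                    raise ValueError(f"unknown config key {key}.{sub}")
                out[key][sub] = sval
        else:
            out[key] = val
    problems = []
    d = out["docking"]
    if not d["auto_scale"]:
        if not (d["stop_radius"] > d["start_radius"] > d["encounter_c2c_max"]):
            problems.append(
                "docking: require stop_radius > start_radius > encounter_c2c_max "
                f"({d['stop_radius']} / {d['start_radius']} / {d['encounter_c2c_max']})"
            )
    h = out["hbonds"]
    if not (0 <= h["d_min"] <= h["d_max"]):
        problems.append(f"hbonds: invalid window [{h['d_min']}, {h['d_max']}]")
    for pair in out["conformers"]:
        if len(pair) != 2 or not all(0 <= a <= 90 for a in pair):
            problems.append(f"conformers: invalid opening-angle pair {pair}")
    if out["clustering"]["n_clusters"] < 1:
        problems.append("clustering: n_clusters must be >= 1")
    if problems:
        raise ValueError("invalid config:\n  " + "\n  ".join(problems))
    return out


def _conformer_label(i: int, pair) -> str:
    return f"conf{i}_{pair[0]:g}_{pair[1]:g}"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _derived_seed(master: int, *indices: int) -> int:
    ss = np.random.SeedSequence([int(master), *[int(i) for i in indices]])
    return int(ss.generate_state(1)[0] % (2**31))


class Pipeline:
    """Stateful runner; every stage reads/writes under the output directory."""

    def __init__(self, config: dict | str | Path | None, outdir):
        self.cfg = validate_config(config)
        self.out = Path(outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "config": self.cfg,
            "seed": self.cfg["seed"],
            "version": __version__,
            "stages": {},
        }
        (self.out / "run.log").touch()

    # -- helpers -----------------------------------------------------------

    def _spec(self, pair) -> FixtureSpec:
        f = self.cfg["fixture"]
        return FixtureSpec(
            core_bp=f["core_bp"], l_dna_bp=f["l_dna_bp"], lh_size=f["lh_size"],
            lh_net_charge=f["lh_net_charge"],
            opening_angle_1=pair[0], opening_angle_2=pair[1],
        )

    @property
    def conformers(self):
        return [
            (_conformer_label(i, p), p) for i, p in enumerate(self.cfg["conformers"])
        ]

    @property
    def variant_labels(self):
        return ["WT"] + list(self.cfg["variants"])

    def _record_stage(self, name: str, outputs: list[Path], counts: dict | None = None):
        self.manifest["stages"][name] = {
            "outputs": {str(p.relative_to(self.out)): _sha256(p) for p in outputs},
            "counts": counts or {},
            "finished": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }

    def _load_models(self, label):
        return load_fixture_files(self.out / "fixtures" / label)

    def _lh_for(self, variant: str, lh):
        return lh if variant == "WT" else apply_variant(lh, variant)

    # -- stages ------------------------------------------------------------

    def stage_fixtures(self):
        outputs = []
        first_label, first_pair = self.conformers[0]
        nuc0 = build_ideal_nucleosome(self._spec(first_pair))
        lh = build_toy_lh(self._spec(first_pair), nuc0)  # one LH for all runs
        for label, pair in self.conformers:
            nuc = nuc0 if label == first_label else build_ideal_nucleosome(
                self._spec(pair)
            )
            paths = write_fixture_files(lh, nuc, self.out / "fixtures" / label)
            outputs.extend(Path(p) for p in paths.values())
        self._record_stage("fixtures", outputs)
        return outputs

    def stage_grid(self):
        g = self.cfg["grid"]
        gdir = self.out / "grids"
        gdir.mkdir(exist_ok=True)
        outputs = []
        for label, _ in self.conformers:
            _, nuc = self._load_models(label)
            grid = debye_huckel_grid(
                nuc.solute, spacing=g["spacing"], padding=g["padding"],
                temperature=g["temperature"], ionic_strength=g["ionic_strength"],
                eps_solvent=g["eps_solvent"], eps_solute=g["eps_solute"],
            )
            path = gdir / f"{label}.dx"
            write_dx_grid(grid, path)
            outputs.append(path)
        self._record_stage("grid", outputs)
        return outputs

    def _docking_field(self, lh, nuc, label) -> DockingField:
        g = self.cfg["grid"]
        grid = read_dx_grid(
            self.out / "grids" / f"{label}.dx",
            temperature=g["temperature"], ionic_strength=g["ionic_strength"],
            eps_solvent=g["eps_solvent"], eps_solute=g["eps_solute"],
            source_center=nuc.solute.geometric_center,
            source_net_charge=nuc.solute.total_charge,
        )
        e = self.cfg["exclusion"]
        excl = build_exclusion_grid(nuc, margin=e["margin"], spacing=e["spacing"])
        mask = np.abs(lh.solute.charges) > 1e-6
        charges = EffectiveChargeSet(
            lh.solute.reference_positions[mask],
            lh.solute.charges[mask],
            lh.solute.radii[mask],
        )
        return DockingField(grid, charges, excl)

    def _sim_config(self, seed: int) -> SimulationConfig:
        d = dict(self.cfg["docking"])
        n_clusters = self.cfg["clustering"]["n_clusters"]
        return SimulationConfig(rng_seed=seed, n_clusters=n_clusters, **d)

    def stage_dock(self):
        if self.cfg["seed"] is None:
            raise ValueError("dock stage: a master seed is mandatory")
        rdir = self.out / "records"
        rdir.mkdir(exist_ok=True)
        outputs = []
        counts = {}
        for ci, (label, _) in enumerate(self.conformers):
            lh0, nuc = self._load_models(label)
            for vi, variant in enumerate(self.variant_labels):
                lh = self._lh_for(variant, lh0)
                field = self._docking_field(lh, nuc, label)
                cfg = self._sim_config(_derived_seed(self.cfg["seed"], vi, ci))
                rs = run_docking(lh, nuc, field, cfg)
                path = rdir / f"{variant}__{label}.csv"
                df = rs.to_dataframe()
                df.to_csv(path, index=False)
                jpath = rdir / f"{variant}__{label}.json"
                jpath.write_text(df.to_json(orient="records", indent=1))
                outputs.extend([path, jpath])
                counts[f"{variant}__{label}"] = {
                    "trajectories": cfg.n_trajectories,
                    "encounters_seen": rs.total_encounters_seen,
                    "records": rs.n,
                    **rs.stats,
                }
                logger.info("dock %s on %s: %d records (%d encounters)",
                            variant, label, rs.n, rs.total_encounters_seen)
        self._record_stage("dock", outputs, counts)
        return outputs

    def _load_recorded_set(self, variant, label, lh) -> RecordedSet:
        df = pd.read_csv(self.out / "records" / f"{variant}__{label}.csv")
        d = self.cfg["docking"]
        return RecordedSet.from_dataframe(
            df, d["capacity"], d["dedup_rmsd"], lh.solute.reference_positions
        )

    def stage_cluster(self):
        cdir = self.out / "clusters"
        cdir.mkdir(exist_ok=True)
        outputs = []
        k = self.cfg["clustering"]["n_clusters"]
        for label, _ in self.conformers:
            lh0, _nuc = self._load_models(label)
            for variant in self.variant_labels:
                lh = self._lh_for(variant, lh0)
                rs = self._load_recorded_set(variant, label, lh)
                clusters = cluster_recorded_set(rs, k=k)
                blob = [
                    {
                        "rank": c.rank,
                        "weighted_size": c.weighted_size,
                        "population_fraction": c.population_fraction,
                        "representative": c.representative,
                        "representative_energy": c.representative_energy,
                        "members": c.member_record_ids,
                    }
                    for c in clusters
                ]
                path = cdir / f"{variant}__{label}.json"
                path.write_text(json.dumps(blob, indent=1))
                outputs.append(path)
        self._record_stage("cluster", outputs)
        return outputs

    def _top_poses(self, variant, label, lh, n=None):
        n = n if n is not None else self.cfg["clustering"]["top_n"]
        clusters = json.loads(
            (self.out / "clusters" / f"{variant}__{label}.json").read_text()
        )
        rs = self._load_recorded_set(variant, label, lh)
        out = []
        for c in sorted(clusters, key=lambda c: c["rank"])[:n]:
            out.append((c["rank"], rs.pose_of(int(c["representative"]))))
        return out

    def stage_classify(self):
        cl = self.cfg["classification"]
        runs = {}
        for label, _ in self.conformers:
            lh0, nuc = self._load_models(label)
            for variant in self.variant_labels:
                lh = self._lh_for(variant, lh0)
                tops = self._top_poses(variant, label, lh, n=1)
                if not tops:
                    continue
                runs[(variant, label)] = classify(
                    lh, tops[0][1], nuc, cutoff=cl["contact_cutoff"],
                    helical_repeat=cl["helical_repeat"], theta_x=cl["theta_x"],
                )
        matrix, shifts = build_match_matrix(runs, reference_variant="WT")
        path = self.out / "configuration_matrix.csv"
        matrix.to_csv(path, index=False)
        spath = self.out / "configuration_shifts.csv"
        pd.DataFrame(
            [{"variant": v, "shifted": n} for v, n in shifts.items()]
        ).to_csv(spath, index=False)
        self._record_stage("classify", [path, spath])
        return [path, spath]

    def stage_hbonds(self):
        h = self.cfg["hbonds"]
        tables = {}
        for label, _ in self.conformers:
            lh0, nuc = self._load_models(label)
            for variant in self.variant_labels:
                lh = self._lh_for(variant, lh0)
                for rank, pose in self._top_poses(variant, label, lh):
                    tables[(variant, label, rank)] = find_hbonds(
                        lh, pose, nuc, d_min=h["d_min"], d_max=h["d_max"],
                        enforce_lower_bound=h["enforce_lower_bound"],
                    )
        rows = []
        for (variant, label, rank), bonds in tables.items():
            for b in bonds:
                rows.append(
                    {
                        "variant": variant, "conformer": label, "cluster_rank": rank,
                        "residue_index": b.lh_residue_index,
                        "residue_name": b.lh_residue_name,
                        "dna_atom_id": b.dna_atom_id,
                        "distance": round(b.distance, 3),
                    }
                )
        path = self.out / "hbonds.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        # per-variant per-residue aggregate over runs and top clusters
        agg_rows = []
        for variant in self.variant_labels:
            sub = {k: v for k, v in tables.items() if k[0] == variant}
            agg = aggregate_hbonds(sub)
            agg["variant"] = variant
            agg_rows.append(agg)
        apath = self.out / "hbonds_aggregate.csv"
        pd.concat(agg_rows, ignore_index=True).to_csv(apath, index=False) \
            if agg_rows else pd.DataFrame().to_csv(apath, index=False)
        self._record_stage("hbonds", [path, apath])
        return [path, apath]

    def stage_report(self):
        path = self.out / "manifest.json"
        path.write_text(json.dumps(self.manifest, indent=1, default=str))
        return [path]

    def run(self, stages=None):
        order = ["fixtures", "grid", "dock", "cluster", "classify", "hbonds",
                 "report"]
        stages = order if stages is None else stages
        handler = logging.FileHandler(self.out / "run.log")
        handler.setLevel(logging.INFO)
        root = logging.getLogger("lhdock")
        prev_level = root.level
        root.setLevel(logging.INFO)
        root.addHandler(handler)
        try:
            for name in stages:
                t0 = time.time()
                try:
                    getattr(self, f"stage_{name}")()
                except Exception as exc:
                    raise RuntimeError(
                        f"pipeline stage {name!r} failed: {exc}"
                    ) from exc
                logger.info("stage %s finished in %.1f s", name, time.time() - t0)
        finally:
            root.removeHandler(handler)
            root.setLevel(prev_level)
            handler.close()
        return self.out


STAGES = ["fixtures", "grid", "dock", "cluster", "classify", "hbonds", "report"]


def run_pipeline(config: dict | str | Path | None, outdir, stages=None) -> Path:
    """Run the pipeline (all stages by default); returns the output dir."""
    return Pipeline(config, outdir).run(stages)
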