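"""End-to-end PAPA-SPT pipeline runs with manifests and caching.

A run config (YAML/JSON-able dict) describes the illumination protocol,
photophysics, labeling mixture and motion models; ``run_pipeline``
executes simulate → classify → spectrum → unmix, writes every artifact
under an output directory, and records a manifest with the seed, config
hash, per-stage status and the SHA-256 of every output. Reruns with an
identical config are bit-identical; stages whose config, upstream inputs
and on-disk outputs are unchanged are skipped, and a corrupted
intermediate (hash mismatch) forces recomputation.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classify import balance, segment_summary, split_trajectories
from .illumination import IlluminationProtocol, parse_protocol
from .spectrum import DiffusionGrid, fraction_bound, infer_spectrum
from .synthetic_data import (
    LabelingModel,
    MixtureComponent,
    MotionModel,
    PhotophysicsModel,
    simulate_photophysics,
    simulate_trajectories,
    simulate_two_state_trajectories,
)
from .trajectories import read_trajectories, write_trajectories
from .unmix import enrichment_report, fit_mixture

__all__ = ["run_pipeline", "demo_config", "load_config"]

STAGES = ("simulate", "classify", "spectrum", "unmix")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _key(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


def load_config(path: "str | Path") -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def demo_config(seed: int = 1) -> dict:
    """A small two-component mixture run that finishes in seconds."""
    return {
        "seed": int(seed),
        "protocol": {
            "string": (
                "4 cycles of 100 R [2 ms], 1 V [2 ms], 200 R [2 ms], "
                "1 G [2 ms], 100 R [2 ms]"
            ),
            "pre_shelving_s": 5.0,
        },
        "photophysics": {
            "p_shelve_per_ms_red": 0.0025,
            "p_bleach_per_ms_red": 0.001,
            "shelvable_fraction": 0.10,
            "k_dr_per_ms_violet": 0.1,
            "k_papa_per_ms_green": 0.1,
            "k_papa_background_per_ms_green": 0.002,
            "p_spont_per_frame": 1e-5,
        },
        "labeling": {
            "components": [
                {"name": "free_double", "n_molecules": 1500, "double_labeled": True},
                {"name": "bound_single", "n_molecules": 1500, "double_labeled": False},
            ]
        },
        "motion": {
            "free_double": {"f_bound": 0.0, "d_free": 8.3},
            "bound_single": {"f_bound": 1.0, "d_bound": 0.01},
        },
        "classify": {"window": 30},
        "spectrum": {"d_min": 0.01, "d_max": 100.0, "n_states": 100},
        "unmix": {"basis_trajectories": 1000},
    }


def _build_protocol(cfg: dict) -> IlluminationProtocol:
    pcfg = cfg["protocol"]
    if isinstance(pcfg, str):
        return parse_protocol(pcfg)
    if "string" in pcfg:
        return parse_protocol(
            pcfg["string"],
            frame_interval_ms=float(pcfg.get("frame_interval_ms", 7.48)),
            pre_shelving_s=float(pcfg.get("pre_shelving_s", 0.0)),
        )
    return IlluminationProtocol.from_dict(pcfg)


def _build_motion(cfg: dict) -> dict[str, MotionModel]:
    return {name: MotionModel(**params) for name, params in cfg["motion"].items()}


def _build_labeling(cfg: dict) -> LabelingModel:
    lcfg = cfg["labeling"]
    if "components" in lcfg:
        comps = tuple(MixtureComponent(**c) for c in lcfg["components"])
        return LabelingModel(components=comps)
    return LabelingModel(**lcfg)


def _grid(cfg: dict) -> DiffusionGrid:
    scfg = cfg.get("spectrum", {})
    d = np.logspace(
        np.log10(scfg.get("d_min", 0.01)),
        np.log10(scfg.get("d_max", 100.0)),
        int(scfg.get("n_states", 100)),
    )
    motion = next(iter(_build_motion(cfg).values()))
    return DiffusionGrid(
        d_values=d,
        sigma_loc=motion.sigma_loc,
        frame_interval_ms=motion.frame_interval_ms,
    )


class _Run:
    def __init__(self, config: dict, outdir: Path):
        self.config = config
        self.outdir = outdir
        self.seed = int(config.get("seed", 0))
        old = outdir / "manifest.json"
        self.previous = json.loads(old.read_text()) if old.exists() else None
        self.manifest = {
            "package_version": __version__,
            "config_hash": _key(config),
            "seed": self.seed,
            "stages": {},
        }

    def _cached(self, name: str, key: str, outputs: list[Path]) -> bool:
        if not self.previous:
            return False
        prev = self.previous.get("stages", {}).get(name)
        if not prev or prev.get("key") != key or prev.get("status") not in (
            "completed",
            "cached",
        ):
            return False
        for p in outputs:
            rel = p.name
            recorded = prev.get("outputs", {}).get(rel)
            if recorded is None or not p.exists() or _sha256(p) != recorded:
                return False
        return True

    def stage(self, name: str, cfg_slice, upstream_keys: list[str], outputs: list[Path], fn):
        key = _key({"config": cfg_slice, "seed": self.seed, "upstream": upstream_keys})
        entry = {"key": key, "outputs": {}, "status": "pending"}
        self.manifest["stages"][name] = entry
        if self._cached(name, key, outputs):
            entry["status"] = "cached"
            entry["outputs"] = {p.name: _sha256(p) for p in outputs}
            return key, True
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - manifest records the failure
            entry["status"] = "failed"
            entry["error"] = f"{type(exc).__name__}: {exc}"
            raise
        finally:
            entry["elapsed_s"] = round(time.perf_counter() - t0, 3)
        entry["status"] = "completed"
        entry["outputs"] = {p.name: _sha256(p) for p in outputs}
        return key, False


def run_pipeline(config: dict, outdir: "str | Path") -> dict:
    """Run the simulate → classify → spectrum → unmix pipeline.

    Returns the manifest (also written to ``outdir/manifest.json``). A
    stage failure is recorded in the manifest with downstream stages
    marked skipped, and the exception is re-raised after the manifest is
    written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run = _Run(config, outdir)

    try:
        protocol = _build_protocol(config)
        motion = _build_motion(config)
        labeling = _build_labeling(config)
        photo = PhotophysicsModel(**config.get("photophysics", {}))
        grid = _grid(config)
        window = int(config.get("classify", {}).get("window", 30))
        n_basis = int(config.get("unmix", {}).get("basis_trajectories", 1000))
        # component A of the unmixing is the double-labeled
        # (sender-carrying) species, so the reported enrichment is that
        # of PAPA's target
        double = {
            c["name"]: bool(c.get("double_labeled", False))
            for c in config.get("labeling", {}).get("components", [])
        }
        comp_names = sorted(motion, key=lambda c: (not double.get(c, False), c))

        traj_csv = outdir / "trajectories.csv"
        papa_csv = outdir / "papa.csv"
        dr_csv = outdir / "dr.csv"
        spec_papa = outdir / "spectrum_papa.csv"
        spec_dr = outdir / "spectrum_dr.csv"
        basis_csvs = {c: outdir / f"spectrum_basis_{c}.csv" for c in comp_names}
        report_json = outdir / "report.json"

        def do_simulate():
            result = simulate_photophysics(photo, labeling, protocol, run.seed)
            ts = simulate_trajectories(motion, result, run.seed + 1)
            write_trajectories(ts, traj_csv)

        k_sim, _ = run.stage(
            "simulate",
            {
                "protocol": protocol.to_dict(),
                "photophysics": config.get("photophysics", {}),
                "labeling": config.get("labeling", {}),
                "motion": config.get("motion", {}),
            },
            [],
            [traj_csv],
            do_simulate,
        )

        def do_classify():
            ts = read_trajectories(traj_csv)
            papa, dr = split_trajectories(ts, protocol, window=window)
            papa, dr = balance(papa, dr, run.seed + 2)
            write_trajectories(papa, papa_csv)
            write_trajectories(dr, dr_csv)

        k_cls, _ = run.stage(
            "classify",
            {"window": window},
            [k_sim],
            [papa_csv, dr_csv],
            do_classify,
        )

        def do_spectrum():
            for src, dst in ((papa_csv, spec_papa), (dr_csv, spec_dr)):
                spec = infer_spectrum(read_trajectories(src), grid)
                spec.to_frame().to_csv(dst, index=False)
            for c in comp_names:
                ts = simulate_two_state_trajectories(
                    n_basis, motion[c], seed=run.seed + 3 + comp_names.index(c)
                )
                infer_spectrum(ts, grid).to_frame().to_csv(
                    basis_csvs[c], index=False
                )

        k_spec, _ = run.stage(
            "spectrum",
            {"spectrum": config.get("spectrum", {}), "n_basis": n_basis},
            [k_cls],
            [spec_papa, spec_dr, *basis_csvs.values()],
            do_spectrum,
        )

        def do_unmix():
            from .spectrum import DiffusionSpectrum
            import pandas as pd

            def load(path):
                df = pd.read_csv(path)
                occ = df["occupation"].to_numpy()
                occ = occ / occ.sum()
                return DiffusionSpectrum(
                    grid=DiffusionGrid(
                        d_values=df["D_um2_s"].to_numpy(),
                        sigma_loc=grid.sigma_loc,
                        frame_interval_ms=grid.frame_interval_ms,
                    ),
                    occupations=occ,
                    n_trajectories=0,
                    n_jumps=0,
                )

            sp, sd = load(spec_papa), load(spec_dr)
            papa_ts = read_trajectories(papa_csv)
            dr_ts = read_trajectories(dr_csv)
            report = {
                "segments": segment_summary(papa_ts, dr_ts),
                "fraction_bound_papa": fraction_bound(sp),
                "fraction_bound_dr": fraction_bound(sd),
            }
            if len(comp_names) >= 2:
                a_name, b_name = comp_names[0], comp_names[-1]
                ba, bb = load(basis_csvs[a_name]), load(basis_csvs[b_name])
                papa_fit = fit_mixture(sp, ba, bb, a_name, b_name)
                dr_fit = fit_mixture(sd, ba, bb, a_name, b_name)
                report["unmix"] = enrichment_report(papa_fit, dr_fit)
            report_json.write_text(json.dumps(report, indent=2))

        run.stage("unmix", {"unmix": config.get("unmix", {})}, [k_spec], [report_json], do_unmix)
    except Exception:
        for name in STAGES:
            if name not in run.manifest["stages"]:
                run.manifest["stages"][name] = {"status": "skipped"}
        raise
    finally:
        (outdir / "manifest.json").write_text(
            json.dumps(run.manifest, indent=2)
        )
    return run.manifest
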