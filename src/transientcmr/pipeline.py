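"""End-to-end reproducible pipeline: simulate -> GOF -> fit -> tau ->
matrix -> LTRE (-> surface), with a checksummed artifact manifest.

Every output embeds the package version, the seed and a config hash, and
an identical (config, seed) pair reproduces byte-identical outputs.
"""

from __future__ import annotations

import argparse
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cjs import ModelSpec, anodev, aic_table, fit, tau_from_fit
from .encounter import build_marray, write_inp
from .gof import estimate_chat, test_3sm, test_3sr
from .lifecycle import (BAD_SEASON, GOOD_SEASON, asymptotic_analysis,
                        build_matrix, vital_rate_sensitivities)
from .ltre import lambda_surface, ltre_decompose
from .simulate import case_study_preset, simulate


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class RunConfig:
    """Pipeline configuration (YAML-serializable)."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    releases_per_cohort: int = 40
    run_surface: bool = False
    surface_points: int = 5
    n_restarts: int = 1
    verbose: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def digest(self) -> str:
        # hash only fields that affect the computation, not presentation
        relevant = {k: v for k, v in self.to_dict().items()
                    if k not in ("out_dir", "verbose")}
        return hashlib.sha256(
            json.dumps(relevant, sort_keys=True).encode()
        ).hexdigest()[:12]


def _header(config: RunConfig) -> str:
    return (f"# transientcmr {__version__} seed={config.seed} "
            f"config={config.digest()}\n")


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig, **kwargs) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, float_format="%.10g", lineterminator="\n", **kwargs)


def _write_json(obj, path: Path, config: RunConfig) -> None:
    payload = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "result": obj,
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_jsonable))


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis chain; returns the artifact manifest.

    Raises :class:`StageError` naming the failing stage; artifacts written
    before the failure are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = (lambda msg: print(msg, file=sys.stderr)) if config.verbose else (lambda msg: None)
    artifacts: list[Path] = []

    def stage(name):
        def deco(fn):
            try:
                log(f"[{name}]")
                return fn()
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return deco

    @stage("simulate")
    def _sim():
        cfg = case_study_preset(seed=config.seed,
                                releases_per_cohort=config.releases_per_cohort)
        data, truth = simulate(cfg)
        path = out / "histories.inp"
        with open(path, "w") as fh:
            fh.write("/* " + _header(config).strip("#\n ") + " */\n")
            write_inp(data, fh)
        artifacts.append(path)
        return cfg, data, truth

    cfg, data, truth = _sim

    @stage("gof")
    def _gof():
        sr = test_3sr(data)
        sm = test_3sm(data)
        chat, fractions = estimate_chat([sr, sm])
        path = out / "gof.json"
        _write_json({"3SR": sr.to_dict(), "3Sm": sm.to_dict(),
                     "c_hat": chat, "fraction_by_component": fractions},
                    path, config)
        artifacts.append(path)
        tab = out / "gof_3sr_tables.csv"
        _write_csv(sr.tables, tab, config, index=False)
        artifacts.append(tab)
        return sr, sm, chat

    sr, sm, chat = _gof

    @stage("fit")
    def _fit():
        marray = build_marray(data)
        mpath = out / "marray.csv"
        _write_csv(marray.to_dataframe().fillna(0), mpath, config, index=False)
        artifacts.append(mpath)
        cov = tuple(cfg.covariate)
        specs = {
            "constant": ModelSpec(tau="group"),
            "covariate": ModelSpec(tau="group+cov", covariate=cov),
            "time": ModelSpec(tau="group+time"),
        }
        fits = {k: fit(marray, s, n_restarts=config.n_restarts,
                       seed=config.seed) for k, s in specs.items()}
        table = aic_table(list(fits.values()))
        apath = out / "aic_table.csv"
        _write_csv(table, apath, config, index=False)
        artifacts.append(apath)
        F, pct, p = anodev(fits["constant"], fits["covariate"], fits["time"])
        jpath = out / "fits.json"
        _write_json({k: f.to_dict() for k, f in fits.items()}
                    | {"anodev": {"F": F, "pct_deviance": pct, "p": p}},
                    jpath, config)
        artifacts.append(jpath)
        return fits

    fits = _fit

    @stage("tau")
    def _tau():
        est = tau_from_fit(fits["covariate"])
        path = out / "tau_estimates.csv"
        _write_csv(est.table, path, config, index=False)
        artifacts.append(path)
        return est

    _ = _tau

    @stage("matrix")
    def _matrix():
        rows = []
        for name, vr in (("good", GOOD_SEASON), ("bad", BAD_SEASON)):
            ana = asymptotic_analysis(build_matrix(vr))
            rows.append({"season": name, "lambda": ana.lam})
        df = pd.DataFrame(rows)
        path = out / "lambda.csv"
        _write_csv(df, path, config, index=False)
        artifacts.append(path)
        spath = out / "vital_rate_sensitivities_good.csv"
        _write_csv(vital_rate_sensitivities(GOOD_SEASON), spath, config)
        artifacts.append(spath)

    _matrix

    @stage("ltre")
    def _ltre():
        report = ltre_decompose(GOOD_SEASON, BAD_SEASON)
        path = out / "ltre.csv"
        _write_csv(report.table, path, config)
        artifacts.append(path)
        jpath = out / "ltre_summary.json"
        _write_json({
            "lambda_good": report.lambda_good,
            "lambda_bad": report.lambda_bad,
            "lambda_delta": report.lambda_delta,
            "sum_of_contributions": report.sum_of_contributions,
            "residual": report.residual,
        }, jpath, config)
        artifacts.append(jpath)

    _ltre

    if config.run_surface:
        @stage("surface")
        def _surface():
            n = config.surface_points
            grid = lambda_surface(GOOD_SEASON, np.linspace(0, 1, n),
                                  np.linspace(0.0, 0.8, n))
            path = out / "lambda_surface.csv"
            _write_csv(grid.to_dataframe(), path, config, index=False)
            artifacts.append(path)

        _surface

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "artifacts": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in artifacts
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def main(argv=None) -> int:
    parser = argparse.ArgumentParser(
        description="Run the transient-CMR demonstration pipeline."
    )
    parser.add_argument("--config", type=str, default=None, help="YAML config file")
    parser.add_argument("--seed", type=int, default=None)
    parser.add_argument("--out", type=str, default=None, help="output directory")
    parser.add_argument("--surface", action="store_true", help="also compute the lambda surface")
    parser.add_argument("--verbose", action="store_true")
    args = parser.parse_args(argv)
    config = RunConfig.from_yaml(args.config) if args.config else RunConfig()
    if args.seed is not None:
        config.seed = args.seed
    if args.out is not None:
        config.out_dir = args.out
    if args.surface:
        config.run_surface = True
    try:
        manifest = run_pipeline(config)
    except StageError as exc:
        print(str(exc), file=sys.stderr)
        return 1
    print(json.dumps(manifest, indent=2, sort_keys=True))
    return 0


if __name__ == "__main__":
    sys.exit(main())
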