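"""File formats: encounter-history CSV, constraint YAML, result TSV.

The on-disk history table is a CSV with columns ``family_id, occasion,
doy, event``; event codes 0-11 (0 = not observed, with an empty date).
Occasions are 1-based years, ``doy`` is 1-based day-of-year.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import Dataset
from .model import FamilyUnitResults
from .params import (ConstraintMap, DepartureModel, ParameterSet,
                     case_study_constraints, scenario_constraints)

HISTORY_COLUMNS = ["family_id", "occasion", "doy", "event"]


class ValidationError(ValueError):
    """Input file violates the history-table schema."""


def validate_history_frame(df: pd.DataFrame,
                           doy_bounds: tuple[float, float] = (80.0, 130.0)
                           ) -> list[str]:
    """Return a list of violations, each naming the offending CSV line.

    Line numbers count the header as line 1, matching what an editor
    shows for the raw file.
    """
    problems: list[str] = []
    missing = [c for c in HISTORY_COLUMNS if c not in df.columns]
    if missing:
        return [f"missing columns: {missing}"]
    lines = df.index.to_numpy() + 2  # header is line 1
    ev = pd.to_numeric(df["event"], errors="coerce")
    bad = df.index[(ev.isna()) | (ev < 0) | (ev > 11) | (ev % 1 != 0)]
    for i in bad:
        problems.append(f"line {lines[i]}: event {df.loc[i, 'event']!r} "
                        "outside 0..11")
    doy = pd.to_numeric(df["doy"], errors="coerce")
    cap = ev.notna() & (ev != 0)
    for i in df.index[cap & doy.isna()]:
        problems.append(f"line {lines[i]}: capture without a doy")
    lo, hi = doy_bounds
    for i in df.index[doy.notna() & ((doy < lo) | (doy > hi))]:
        problems.append(f"line {lines[i]}: doy {doy[i]} outside "
                        f"[{lo}, {hi}]")
    for fid, grp in df.groupby("family_id", sort=False):
        occ = pd.to_numeric(grp["occasion"], errors="coerce")
        if occ.isna().any():
            problems.append(f"family {fid}: non-integer occasion")
            continue
        if not occ.is_monotonic_increasing or occ.duplicated().any():
            first_bad = grp.index[0]
            problems.append(f"family {fid} (line {lines[first_bad]}): "
                            "occasions not strictly increasing")
        if ev[grp.index[0]] == 0:
            problems.append(f"family {fid} (line {lines[grp.index[0]]}): "
                            "first record is not a capture")
    return problems


def read_histories(path: str | Path, T: int | None = None,
                   doy_bounds: tuple[float, float] = (80.0, 130.0)) -> Dataset:
    """Read and validate an encounter-history CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    problems = validate_history_frame(df, doy_bounds)
    if problems:
        raise ValidationError(
            f"{path.name}: {len(problems)} problem(s)\n  " +
            "\n  ".join(problems))
    return Dataset.from_frame(df, T=T)


def write_histories(data: Dataset, path: str | Path) -> None:
    df = data.to_frame()
    # 17 significant digits: float64 dates survive the round-trip exactly
    df.to_csv(path, index=False, float_format="%.17g")


def write_truth_sidecar(params: ParameterSet, seed: int,
                        path: str | Path) -> None:
    """JSON sidecar recording the generating parameters and seed."""
    payload = {
        "seed": seed,
        "phi": params.phi.tolist(), "s": params.s.tolist(),
        "kappa": params.kappa, "beta": params.beta.tolist(),
        "gamma": params.gamma.tolist(), "p": params.p.tolist(),
        "pi": params.pi.tolist(),
        "departure": {
            "kind": params.departure.kind,
            "alpha0": params.departure.alpha0,
            "intercept": params.departure.intercept,
            "slope": params.departure.slope,
            "simultaneous_siblings": params.departure.simultaneous_siblings,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_constraints(path: str | Path) -> ConstraintMap:
    """Read a constraint specification from YAML.

    Either ``preset: case_study | scenario_constant | scenario_seasonal``
    or an explicit mapping with keys ``share`` (list of name lists),
    ``fix`` (name -> value), ``pi_free``, ``estimate_alpha0``.
    """
    spec = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(spec, dict):
        raise ValidationError("constraint file must be a mapping")
    if "preset" in spec:
        presets = {
            "case_study": case_study_constraints,
            "scenario_constant": lambda: scenario_constraints("constant"),
            "scenario_seasonal": lambda: scenario_constraints("seasonal"),
        }
        name = spec["preset"]
        if name not in presets:
            raise ValidationError(f"unknown preset {name!r}")
        return presets[name]()
    known = {"share", "fix", "pi_free", "estimate_alpha0"}
    unknown = set(spec) - known
    if unknown:
        raise ValidationError(f"unknown keys in constraint file: "
                              f"{sorted(unknown)}")
    return ConstraintMap(
        share=tuple(tuple(g) for g in spec.get("share", [])),
        fix=dict(spec.get("fix", {})),
        pi_free=bool(spec.get("pi_free", True)),
        estimate_alpha0=bool(spec.get("estimate_alpha0", False)),
    )


def write_results(results: FamilyUnitResults, path: str | Path,
                  manifest: dict | None = None) -> None:
    """Write estimates as TSV plus a JSON run manifest alongside."""
    path = Path(path)
    results.to_frame().to_csv(path, sep="\t", index=False,
                              float_format="%.6g")
    meta = {
        "backend": results.backend,
        "loglik": results.llf,
        "converged": bool(results.converged),
        "n_free": results.n_free,
        "n_families": results.nobs,
    }
    if manifest:
        meta.update(manifest)
    path.with_suffix(path.suffix + ".manifest.json").write_text(
        json.dumps(meta, indent=1, default=str))


def read_results_frame(path: str | Path) -> pd.DataFrame:
    """Read a fitted-parameter TSV back as a DataFrame."""
    return pd.read_csv(path, sep="\t")


def params_from_results_frame(df: pd.DataFrame,
                              template: ParameterSet | None = None
                              ) -> ParameterSet:
    """Rebuild a ParameterSet from a fitted-parameter table.

    Shared groups appear as ``name1=name2=...`` labels; every member
    receives the group's estimate. Parameters absent from the table keep
    their template values.
    """
    from .params import default_parameters

    template = template if template is not None else default_parameters()
    values: dict[str, float] = {}
    pi = template.pi.copy()
    for label, est in zip(df["parameter"], df["estimate"]):
        for name in str(label).split("="):
            name = name.removeprefix("logit_")
            if name.startswith("pi"):
                pi[int(name[2:]) - 1] = float(est)
            else:
                values[name] = float(est)
    pi = pi / pi.sum()
    return template.with_values(values, pi=pi)
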