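"""File I/O, configuration and reporting.

The on-disk record format is a plain CSV with header

    vesicle_id, trial_id, gra_mole_percent, radius_um, sigma_mn_per_m,
    rupture_time_s, censored

in laboratory units (um, mN/m, s); ``censored`` is true/false and a censored
row leaves ``rupture_time_s`` empty.  All conversion to SI happens here, so
the computational modules never see a um or a mN/m.  Reports are rendered as
JSON or aligned text, one row per condition (rate constant with its error,
rupture probability at the window end, and -- when rates at three or more
tensions exist for a peptide content -- the inferred pore-edge tension),
and every report embeds the package version, the seed and a digest of the
active configuration for provenance.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .electromechanics import MembraneConstants
from .edge_tension import TensionRatePoint, fit_edge_tension
from .energetics import DEFAULT_B_N_PER_M
from .survival import RateFit, VesicleRecord, aggregate_rate, rupture_probability

__all__ = [
    "RunConfig",
    "load_config",
    "read_records",
    "write_records",
    "analyze",
    "report",
]

CSV_COLUMNS = [
    "vesicle_id",
    "trial_id",
    "gra_mole_percent",
    "radius_um",
    "sigma_mn_per_m",
    "rupture_time_s",
    "censored",
]

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


@dataclass(frozen=True)
class RunConfig:
    """Run-level configuration: constants, model scalars and estimator choices."""

    constants: MembraneConstants = field(default_factory=MembraneConstants)
    B: float = DEFAULT_B_N_PER_M
    estimator: str = "ls"
    weighting: str = "none"
    pooled: bool = False
    bootstrap: int = 0
    seed: int = 0

    def digest(self) -> str:
        """Short stable hash of the configuration, for report provenance."""
        payload = {
            "epsilon_m": self.constants.epsilon_m,
            "epsilon_0": self.constants.epsilon_0,
            "h_m": self.constants.h,
            "h_e_m": self.constants.h_e,
            "temperature_K": self.constants.T,
            "B_n_per_m": self.B,
            "estimator": self.estimator,
            "weighting": self.weighting,
            "pooled": self.pooled,
            "bootstrap": self.bootstrap,
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str) -> RunConfig:
    """Read a YAML config; unknown keys are rejected to catch typos.

    Recognized keys: epsilon_m, epsilon_0, h_m, h_e_m, temperature_K,
    B_mn_per_m, estimator, weighting, pooled, bootstrap, seed.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {
        "epsilon_m",
        "epsilon_0",
        "h_m",
        "h_e_m",
        "temperature_K",
        "B_mn_per_m",
        "estimator",
        "weighting",
        "pooled",
        "bootstrap",
        "seed",
    }
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    defaults = MembraneConstants()
    constants = MembraneConstants(
        epsilon_m=raw.get("epsilon_m", defaults.epsilon_m),
        epsilon_0=raw.get("epsilon_0", defaults.epsilon_0),
        h=raw.get("h_m", defaults.h),
        h_e=raw.get("h_e_m", defaults.h_e),
        T=raw.get("temperature_K", defaults.T),
    )
    return RunConfig(
        constants=constants,
        B=raw.get("B_mn_per_m", DEFAULT_B_N_PER_M * 1e3) * 1e-3,
        estimator=raw.get("estimator", "ls"),
        weighting=raw.get("weighting", "none"),
        pooled=bool(raw.get("pooled", False)),
        bootstrap=int(raw.get("bootstrap", 0)),
        seed=int(raw.get("seed", 0)),
    )


def _parse_bool(value, row: int) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"row {row}: censored flag {value!r} is not true/false")


def read_records(path: str, window: float = 60.0) -> list[VesicleRecord]:
    """Read vesicle records from CSV, validating row by row.

    Row numbers in error messages count data rows from 2 (the header is
    row 1), matching what a spreadsheet shows.  Laboratory units in the file
    (um, mN/m) are converted to SI on the way in.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    records = []
    for i, row in df.iterrows():
        rownum = i + 2
        try:
            censored = _parse_bool(row["censored"], rownum)
            time_field = str(row["rupture_time_s"]).strip()
            if censored and time_field:
                raise ValueError(
                    f"row {rownum}: censored=true contradicts rupture_time_s={time_field!r}"
                )
            if not censored and not time_field:
                raise ValueError(f"row {rownum}: uncensored row lacks a rupture time")
            try:
                gra = float(row["gra_mole_percent"])
                radius_um = float(row["radius_um"])
                sigma_mn = float(row["sigma_mn_per_m"])
                rupture_time = float(time_field) if time_field else None
            except ValueError as exc:
                raise ValueError(f"row {rownum}: non-numeric field ({exc})") from None
            records.append(
                VesicleRecord(
                    vesicle_id=str(row["vesicle_id"]),
                    trial_id=str(row["trial_id"]),
                    gra_mole_percent=gra,
                    radius=radius_um * 1e-6,
                    sigma_e=sigma_mn * 1e-3,
                    rupture_time=rupture_time,
                    censored=censored,
                    window=window,
                )
            )
        except ValueError as exc:
            msg = str(exc)
            if not msg.startswith("row "):
                msg = f"row {rownum}: {msg}"
            raise ValueError(f"{path}: {msg}") from None
    if not records:
        raise ValueError(f"{path}: no data rows")
    return records


def write_records(records: Sequence[VesicleRecord], path: str) -> None:
    """Write vesicle records to the CSV schema, converting SI back to lab units."""
    rows = []
    for r in records:
        rows.append(
            {
                "vesicle_id": r.vesicle_id,
                "trial_id": r.trial_id,
                "gra_mole_percent": r.gra_mole_percent,
                "radius_um": r.radius * 1e6,
                "sigma_mn_per_m": r.sigma_e * 1e3,
                "rupture_time_s": "" if r.censored else r.rupture_time,
                "censored": "true" if r.censored else "false",
            }
        )
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def analyze(records: Sequence[VesicleRecord], config: RunConfig | None = None) -> dict:
    """Full analysis of a record set, grouped by condition.

    Per (peptide content, tension) cell: aggregated rate constant and the
    rupture probability at the window end.  Per peptide content with rates
    at >= 3 tensions: the pore-edge tension from the linearized rate law.
    Returns a plain dict ready for :func:`report`.
    """
    if config is None:
        config = RunConfig()
    records = list(records)
    cells = []
    by_cell: dict[tuple[float, float], list[VesicleRecord]] = {}
    for r in records:
        by_cell.setdefault((r.gra_mole_percent, r.sigma_e), []).append(r)
    rate_points: dict[float, list[TensionRatePoint]] = {}
    for (gra, sigma), grp in sorted(by_cell.items()):
        window = grp[0].window
        p_rup = rupture_probability(grp, window)
        try:
            fit = aggregate_rate(grp, method=config.estimator, pooled=config.pooled)
            k_r, k_se = fit.k_r, fit.k_r_se
            if k_r > 0:
                rate_points.setdefault(gra, []).append(
                    TensionRatePoint(
                        sigma_e=sigma, k_r=k_r, k_r_se=k_se, gra_mole_percent=gra
                    )
                )
        except ValueError:
            k_r, k_se = float("nan"), float("nan")
        cells.append(
            {
                "gra_mole_percent": gra,
                "sigma_mn_per_m": sigma * 1e3,
                "n_vesicles": len(grp),
                "k_r_per_s": k_r,
                "k_r_se_per_s": k_se,
                "p_rup_window": p_rup,
            }
        )
    edge_fits = []
    for gra, pts in sorted(rate_points.items()):
        if len({p.sigma_e for p in pts}) < 3:
            continue
        try:
            fit = fit_edge_tension(
                pts, B=config.B, constants=config.constants, weighting=config.weighting
            )
        except ValueError:
            continue
        edge_fits.append(
            {
                "gra_mole_percent": gra,
                "Gamma_pN": fit.Gamma * 1e12,
                "Gamma_se_pN": fit.Gamma_se * 1e12,
                "A_per_s": fit.A,
                "r_squared": fit.r_squared,
                "n_points": fit.n_points,
            }
        )
    return {
        "version": __version__,
        "seed": config.seed,
        "config_digest": config.digest(),
        "conditions": cells,
        "edge_tension": edge_fits,
    }


def report(analysis: dict, format: str = "json") -> str:
    """Render an analysis dict as JSON or an aligned text table."""
    if format == "json":
        return json.dumps(analysis, indent=2, allow_nan=True)
    if format != "text":
        raise ValueError(f"format must be 'json' or 'text', got {format!r}")
    lines = [
        f"guvkinetics {analysis['version']}  seed={analysis['seed']}  "
        f"config={analysis['config_digest']}",
        "",
        f"{'GrA%':>6} {'sigma(mN/m)':>12} {'n':>4} {'k_r(1/s)':>10} "
        f"{'se':>8} {'P_rup':>6}",
    ]
    for c in analysis["conditions"]:
        lines.append(
            f"{c['gra_mole_percent']:>6.3g} {c['sigma_mn_per_m']:>12.3g} "
            f"{c['n_vesicles']:>4d} {c['k_r_per_s']:>10.4g} "
            f"{c['k_r_se_per_s']:>8.2g} {c['p_rup_window']:>6.3f}"
        )
    if analysis["edge_tension"]:
        lines += ["", f"{'GrA%':>6} {'Gamma(pN)':>10} {'se':>6} {'A(1/s)':>10} {'R2':>6}"]
        for e in analysis["edge_tension"]:
            lines.append(
                f"{e['gra_mole_percent']:>6.3g} {e['Gamma_pN']:>10.3f} "
                f"{e['Gamma_se_pN']:>6.2f} {e['A_per_s']:>10.4g} {e['r_squared']:>6.3f}"
            )
    return "\n".join(lines)
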