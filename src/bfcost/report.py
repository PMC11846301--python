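"""Table writers and the run manifest.

All model arithmetic stays unrounded; rounding happens here, at write time:
case and episode counts round half-away-from-zero to whole units, dollars
round to whole USD.  Currency symbols never enter numeric cells.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .params import DISEASES, ParameterSet
from .scenarios import (ANNUAL_DISEASES, CHILDHOOD_DISEASES, ScenarioRun,
                        SensitivityResult)

__all__ = ["RunManifest", "round_half_away", "burden_frame",
           "write_burden_table", "sensitivity_frame",
           "write_sensitivity_table", "parameter_digest"]

_BLOCKS = (("annual", ANNUAL_DISEASES), ("childhood-14y", CHILDHOOD_DISEASES))


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def parameter_digest(params: ParameterSet) -> str:
    """SHA-256 of the canonical serialized registry; changes iff any
    parameter changes."""
    doc = json.dumps(params.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(doc.encode()).hexdigest()


@dataclass
class RunManifest:
    """Provenance for one model run, written beside its outputs."""

    parameter_digest: str
    scenarios: list[str]
    seed: int | None = None
    warnings: list[str] = field(default_factory=list)
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat())

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


def burden_frame(run: ScenarioRun,
                 scenarios: list[str] | None = None) -> pd.DataFrame:
    """Burden table: one row per disease × scenario plus per-block totals."""
    names = scenarios or [s.name for s in
                          next(iter(run.scenario_matrix.values()))]
    rows = []
    for horizon, diseases in _BLOCKS:
        for scenario in names:
            for disease in diseases:
                if scenario not in {s.name for s in
                                    run.scenario_matrix[disease]}:
                    continue
                res = run.result(disease, scenario)
                sav = run.saving(disease, scenario)
                rows.append({
                    "disease": disease, "scenario": scenario,
                    "horizon": horizon,
                    "cases": round_half_away(res.cases),
                    "cases_averted": round_half_away(sav.cases_averted),
                    "hospitalizations_averted": round_half_away(
                        sav.hospitalizations_averted),
                    "outpatient_visits_averted": round_half_away(
                        sav.outpatient_visits_averted),
                    "cost_usd": round_half_away(res.cost_usd),
                    "cost_saved_usd": round_half_away(sav.cost_saved_usd),
                })
            block_rows = [r for r in rows
                          if r["horizon"] == horizon
                          and r["scenario"] == scenario
                          and r["disease"] in diseases]
            if block_rows:
                rows.append({
                    "disease": "Total", "scenario": scenario,
                    "horizon": horizon,
                    **{col: sum(r[col] for r in block_rows)
                       for col in ("cases", "cases_averted",
                                   "hospitalizations_averted",
                                   "outpatient_visits_averted",
                                   "cost_usd", "cost_saved_usd")},
                })
    columns = ["disease", "scenario", "horizon", "cases", "cases_averted",
               "hospitalizations_averted", "outpatient_visits_averted",
               "cost_usd", "cost_saved_usd"]
    return pd.DataFrame(rows, columns=columns)


def write_burden_table(run: ScenarioRun, destination: str | Path,
                       scenarios: list[str] | None = None) -> Path:
    """Write the burden table as CSV and return the path."""
    destination = Path(destination)
    burden_frame(run, scenarios).to_csv(destination, index=False,
                                        lineterminator="\n")
    return destination


def sensitivity_frame(results: list[SensitivityResult]) -> pd.DataFrame:
    order = {d: i for i, d in enumerate(DISEASES)}
    rows = sorted(
        ({"disease": r.disease, "scenario": r.scenario,
          "varied_parameter": r.varied_parameter,
          "savings_low_usd": round_half_away(r.low),
          "savings_mean_usd": round_half_away(r.mean),
          "savings_high_usd": round_half_away(r.high)} for r in results),
        key=lambda row: (order[row["disease"]], row["scenario"]))
    return pd.DataFrame(rows, columns=[
        "disease", "scenario", "varied_parameter", "savings_low_usd",
        "savings_mean_usd", "savings_high_usd"])


def write_sensitivity_table(results: list[SensitivityResult],
                            destination: str | Path) -> Path:
    destination = Path(destination)
    sensitivity_frame(results).to_csv(destination, index=False,
                                      lineterminator="\n")
    return destination
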