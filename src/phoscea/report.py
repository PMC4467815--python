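"""Tabular exports: base-case results table, scenario table, PSA plane
and CEAC, plus a run manifest.

Cohort monetary results are reported in € thousand and per-patient
results in €, each column labelled; rounding (€ to units, QALYs to three
decimals) happens here and only here.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from .decision_tree import Strategy, responder_counts
from .economics import ComparisonResult
from .parameters import ModelParameters, Stage, parameters_to_dict
from .sensitivity import PSAResult


def parameters_hash(params: ModelParameters) -> str:
    """Content hash of the full parameter set (stable across reloads)."""
    payload = json.dumps(parameters_to_dict(params), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_manifest(params: ModelParameters, seed: int | None = None,
                 config_path: str | None = None, **flags) -> dict:
    return {
        "config": config_path or "<bundled base case>",
        "parameters_sha256_16": parameters_hash(params),
        "seed": seed if seed is not None else params.settings.seed,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "flags": flags,
    }


def _fmt_icer(icer) -> str:
    return icer if isinstance(icer, str) else f"{icer:,.0f}"


def basecase_table(res: ComparisonResult, params: ModelParameters,
                   full_precision: bool = False) -> pd.DataFrame:
    """Results table: responders, health outcomes, cost components and the
    incremental comparison, for both strategies."""
    n = params.settings.cohort_size

    def money_k(x):
        return x / 1e3 if full_precision else round(x / 1e3)

    def qty(x, nd=3):
        return x if full_precision else round(x, nd)

    resp_cb = responder_counts(params, Strategy.CB_CONTINUED, Stage.PREDIALYSIS)
    resp_lc = responder_counts(params, Strategy.LC_SECOND_LINE, Stage.PREDIALYSIS)
    rows = [
        ("Responders in predialysis (n)", qty(resp_cb, 1), qty(resp_lc, 1),
         qty(resp_lc - resp_cb, 1)),
        ("Life years (cohort)", qty(res.cb.life_years), qty(res.lc.life_years),
         qty(res.ce.delta_ly)),
        ("Dialysis-free years gained (cohort)", 0.0, qty(res.dialysis_free_years_gained),
         qty(res.dialysis_free_years_gained)),
        ("QALYs (cohort)", qty(res.cb.qalys), qty(res.lc.qalys), qty(res.ce.delta_qalys)),
        ("QALYs per patient", qty(res.cb.qalys / n), qty(res.lc.qalys / n),
         qty(res.ce.delta_qalys / n)),
        ("Drug costs (EUR thousand)", money_k(res.cb.drug_cost), money_k(res.lc.drug_cost),
         money_k(res.lc.drug_cost - res.cb.drug_cost)),
        ("Dialysis costs (EUR thousand)", money_k(res.cb.dialysis_cost),
         money_k(res.lc.dialysis_cost), money_k(res.lc.dialysis_cost - res.cb.dialysis_cost)),
        ("Total costs (EUR thousand)", money_k(res.cb.total_cost), money_k(res.lc.total_cost),
         money_k(res.ce.delta_cost)),
        ("Total cost per patient (EUR)",
         res.cb.total_cost / n if full_precision else round(res.cb.total_cost / n),
         res.lc.total_cost / n if full_precision else round(res.lc.total_cost / n),
         res.ce.delta_cost / n if full_precision else round(res.ce.delta_cost / n)),
        ("ICER per QALY gained (EUR)", "", "", _fmt_icer(res.ce.icer_per_qaly)),
        ("ICER per life year gained (EUR)", "", "", _fmt_icer(res.ce.icer_per_ly)),
        ("Net monetary benefit (EUR thousand)", "", "", money_k(res.ce.nmb)),
    ]
    return pd.DataFrame(rows, columns=["quantity", "continued_CB", "second_line_LC",
                                       "difference"])


def scenarios_table(results: dict[str, ComparisonResult],
                    descriptions: dict[str, str] | None = None) -> pd.DataFrame:
    """One row per scenario, mirroring the one-way sensitivity layout."""
    rows = []
    for sid, res in results.items():
        rows.append({
            "scenario": sid,
            "description": (descriptions or {}).get(sid, ""),
            "qalys_cb": round(res.cb.qalys, 3),
            "qalys_lc": round(res.lc.qalys, 3),
            "delta_qalys": round(res.ce.delta_qalys, 3),
            "cost_cb_thousand": round(res.cb.total_cost / 1e3),
            "cost_lc_thousand": round(res.lc.total_cost / 1e3),
            "delta_cost_thousand": round(res.ce.delta_cost / 1e3),
            "icer_per_qaly": _fmt_icer(res.ce.icer_per_qaly),
        })
    return pd.DataFrame(rows)


def psa_tables(psa: PSAResult) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """(plane, ceac, summary) exports for a PSA run."""
    plane = psa.points.copy()
    ceac = pd.DataFrame({"lambda": list(psa.ceac), "fraction_cost_effective":
                         list(psa.ceac.values())})
    summary = {
        "n_iterations": psa.n_iterations,
        "seed": psa.seed,
        "fraction_dominant": psa.fraction_dominant,
        "fraction_cost_effective_at_30000": psa.ceac.get(30_000.0),
        "fraction_cost_effective_at_45000": psa.ceac.get(45_000.0),
        "mean_delta_cost": float(psa.points["delta_cost"].mean()),
        "mean_delta_qalys": float(psa.points["delta_qalys"].mean()),
    }
    return plane, ceac, summary


def write_outputs(out_dir: str | Path, manifest: dict,
                  tables: dict[str, pd.DataFrame] | None = None,
                  jsons: dict[str, dict] | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    for name, df in (tables or {}).items():
        df.to_csv(out / f"{name}.csv", index=False)
    for name, obj in (jsons or {}).items():
        with open(out / f"{name}.json", "w") as fh:
            json.dump(obj, fh, indent=2)
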