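"""Multiplicity adjustment, sample-size utility, and the end-to-end
pipeline from a raw (or simulated) trial CSV to change-from-baseline and
mediation tables.
"""

from __future__ import annotations

import hashlib
import json
import math
import sys
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigError, SchemaError

__all__ = ["fdr_adjust", "required_sample_size", "run_pipeline"]

#: Outcomes modelled longitudinally by the pipeline.
PIPELINE_OUTCOMES = ["al_mm", "cct_um", "acd_mm", "lt_mm", "vcd_mm",
                     "cht_um", "se_d", "km_d", "lp_d"]


def fdr_adjust(pvalues, family: str | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sort ascending, multiply p_(i) by m/i, enforce monotonicity by a
    cumulative minimum from the largest rank, cap at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError(f"p-values outside [0, 1] in family {family!r}")
    return multipletests(p, method="fdr_bh")[1]


def required_sample_size(alpha: float, power: float, sd: float,
                         detectable_difference: float,
                         use_t: bool = False) -> int:
    """Participants per group for a two-sided two-sample comparison.

    Normal approximation: ceil(2 (z_{1-a/2} + z_{power})^2 sd^2 / diff^2).
    With ``use_t`` the normal quantiles are replaced by t quantiles at
    2(n-1) df and iterated to a fixed point.
    """
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if sd <= 0:
        raise ValueError("sd must be positive")
    if detectable_difference == 0:
        raise ZeroDivisionError("detectable difference of zero: sample size diverges")
    za = stats.norm.ppf(1.0 - alpha / 2.0)
    zb = stats.norm.ppf(power)
    n = math.ceil(2.0 * (za + zb) ** 2 * sd ** 2 / detectable_difference ** 2)
    if not use_t:
        return n
    for _ in range(100):
        df = max(2 * (n - 1), 1)
        ta = stats.t.ppf(1.0 - alpha / 2.0, df)
        tb = stats.t.ppf(power, df)
        n_new = math.ceil(2.0 * (ta + tb) ** 2 * sd ** 2 / detectable_difference ** 2)
        if n_new == n:
            return n
        n = n_new
    return n


# ---------------------------------------------------------------------- #

def _log(lines: list, level: str, msg: str) -> None:
    stamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
    lines.append(f"{stamp} [{level}] {msg}")


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Run biometry derivation -> eye averaging -> per-outcome cLMM ->
    mediation at months 3 and 6 -> FDR, and write the artifact bundle.

    ``config`` keys: ``input_csv`` (path to a raw long-format table) *or*
    ``simulate`` (true / a SimulationConfig-shaped mapping), ``seed``,
    ``out_dir``, optional ``bennett`` (c1/c2/n/vertex_mm overrides).

    Writes ``table2.csv`` (change from baseline per outcome), ``table3.csv``
    (mediation decomposition), ``summary.json`` and ``run.log``; returns
    the bundle as a dict of DataFrames.  Outputs are a pure function of
    (input CSV, config, seed).
    """
    from . import biometry
    from .clmm import ConstrainedLMM
    from .mediation import MediationModel
    from .simulate import SimulationConfig, simulate_trial

    out_dir = Path(out_dir or config.get("out_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 20190501))
    log: list[str] = []
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]
    _log(log, "INFO", f"pipeline start seed={seed} config_hash={cfg_hash}")
    _log(log, "INFO", f"python={sys.version.split()[0]} numpy={np.__version__} "
         f"pandas={pd.__version__}")

    if config.get("input_csv"):
        raw = pd.read_csv(config["input_csv"])
        biometry.validate_schema(raw)
        _log(log, "INFO", f"loaded {len(raw)} rows from {config['input_csv']}")
    elif config.get("simulate"):
        sim = config["simulate"]
        sim_cfg = SimulationConfig(**sim) if isinstance(sim, dict) else SimulationConfig()
        raw = simulate_trial(sim_cfg, seed=seed).data
        _log(log, "INFO", f"simulated trial: {len(raw)} rows, seed {seed}")
    else:
        raise ConfigError("config must provide 'input_csv' or 'simulate'")

    constants = biometry.BennettConstants(**config.get("bennett", {}))
    derived = biometry.derive_table(raw, constants)
    avg = biometry.average_eyes_table(derived)
    _log(log, "INFO", f"derived + eye-averaged: {len(avg)} participant-visits")

    # --- Table-2-shaped: per-outcome cLMM ------------------------------- #
    t2_rows = []
    reference = config.get("reference", "placebo")
    for outcome in PIPELINE_OUTCOMES:
        try:
            res = ConstrainedLMM(avg, outcome, reference=reference).fit()
        except Exception as err:  # report, do not abort the bundle
            _log(log, "ERROR", f"cLMM failed for {outcome}: {err}")
            continue
        if not res.converged:
            _log(log, "WARN", f"cLMM did not fully converge for {outcome}")
        tab = res.table()
        t2_rows.append(tab)
        _log(log, "INFO", f"cLMM {outcome}: loglik {res.reml_loglik:.2f}, "
             f"n {res.n_used}")
    table2 = pd.concat(t2_rows, ignore_index=True)
    # FDR family: all pairwise-vs-placebo contrasts across outcomes and visits
    mask = table2["comparison"].str.contains(" - ")
    table2["family"] = np.where(mask, "table2:vs-placebo", "")
    adj = np.full(len(table2), np.nan)
    adj[mask.to_numpy()] = fdr_adjust(table2.loc[mask, "p"].to_numpy(),
                                      family="table2:vs-placebo")
    table2["adj_p"] = adj

    # --- Table-3-shaped: mediation at months 3 and 6 -------------------- #
    t3_rows = []
    for visit in (3, 6):
        chg = biometry.changes_from_baseline(
            avg, visit, outcomes=("se_d", "al_mm", "lp_d", "cht_um"))
        # ChT is analysed in mm inside the mediation; I/O stays in um
        chg["d_cht_mm"] = chg["d_cht_um"] / 1000.0
        _log(log, "INFO", f"mediation month {visit}: converted d_cht_um -> mm; "
             f"{chg.dropna().shape[0]} complete cases")
        res = MediationModel(chg, dependent="d_se_d",
                             mediators=("d_al_mm", "d_lp_d", "d_cht_mm"),
                             reference=reference).fit()
        tab = res.effect_table()
        tab.insert(0, "visit", visit)
        t3_rows.append(tab)
    table3 = pd.concat(t3_rows, ignore_index=True)
    mask3 = ~table3["effect"].isin(["indirect", "total"])
    table3["family"] = np.where(mask3, "table3:effect-differences", "")
    adj3 = np.full(len(table3), np.nan)
    if "diff_p" in table3:
        adj3[mask3.to_numpy()] = fdr_adjust(table3.loc[mask3, "diff_p"].to_numpy(),
                                            family="table3:effect-differences")
    table3["diff_adj_p"] = adj3

    # --- write bundle ---------------------------------------------------- #
    table2.to_csv(out_dir / "table2.csv", index=False)
    table3.to_csv(out_dir / "table3.csv", index=False)
    summary = {
        "seed": seed,
        "config_hash": cfg_hash,
        "n_participants": int(avg["pid"].nunique()),
        "outcomes_fit": sorted(table2["outcome"].unique().tolist()),
        "mediation_n": {str(v): int((table3["visit"] == v).any() and
                                    len(avg[avg["month"] == v]))
                        for v in (3, 6)},
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    _log(log, "INFO", "pipeline complete")
    (out_dir / "run.log").write_text("\n".join(log) + "\n")
    return {"table2": table2, "table3": table3, "summary": summary}
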