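"""Simulation studies quantifying pipeline performance on synthetic screens.

These are the package's own validation experiments: benchmark-concentration
recovery and bootstrap-CI coverage over many simulated sigmoid screens, and
intended-label recovery over the canonical 12-scenario battery.  They are
imported by the test suite and the acceptance script so the numbers are
always recomputed, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import screen, simulate
from .fitting import bmc_ci, fit_curve
from .pipeline import default_config, run_pipeline


@dataclass
class RecoveryResult:
    n_screens: int
    errors_log10: np.ndarray  # log10(BMC_hat / BMC_true) per screen
    covered: np.ndarray  # bootstrap CI contains the true BMC

    @property
    def median_abs_log10_error(self) -> float:
        return float(np.median(np.abs(self.errors_log10)))

    @property
    def coverage(self) -> float:
        return float(np.mean(self.covered))


def bmc_recovery_experiment(
    n_screens: int = 200,
    noise_sd: float = 5.0,
    n_boot: int = 200,
    bmr: float = 20.0,
    n_replicates: int = 5,
    seed: int = 0,
) -> RecoveryResult:
    """Fit many noisy sigmoid screens and compare BMC estimates to truth.

    Each screen draws a decreasing sigmoid with log-uniform EC50 in
    [0.2, 4] µM and Hill slope uniform in [1, 3] (full effect, top 100 to
    bottom 0), plates it on the battery's 7-point 1:3 dilution from 20 µM
    with ``n_replicates`` wells plus solvent controls, renormalizes to the
    observed control mean, fits, and derives the BMC with its percentile
    bootstrap CI.
    """
    rng = np.random.default_rng(seed)
    dil = simulate.DilutionSpec()
    conc = dil.concentrations()
    errors, covered = [], []
    for i in range(n_screens):
        ec50 = float(10 ** rng.uniform(np.log10(0.2), np.log10(4.0)))
        hill = float(rng.uniform(1.0, 3.0))
        spec = simulate.TrueCurveSpec(
            "sigmoid_decreasing", 0.0, 100.0, ec50, hill, noise_sd=noise_sd
        )
        true_bmc = spec.true_bmc(bmr, c_max=dil.top_conc)
        wells = simulate.simulate_endpoint(
            spec, conc, n_replicates, np.random.default_rng(rng.integers(2**31))
        )
        wells["compound"] = f"S{i:03d}"
        wells["endpoint"] = "DNT"
        normalized = screen.percent_of_control(wells.rename(columns={"value_pct_control": "value"}))
        ser = screen.build_series(normalized)[(f"S{i:03d}", "DNT")]
        fit = fit_curve(ser, "sigmoid")
        est = bmc_ci(ser, fit, bmr, "decrease", n_boot=n_boot, seed=int(rng.integers(2**31)))
        if est.censored:
            # count a censored estimate as a miss at the range boundary
            errors.append(np.log10(dil.top_conc / true_bmc))
            covered.append(False)
            continue
        errors.append(np.log10(est.bmc / true_bmc))
        covered.append(bool(est.ci_lower <= true_bmc <= est.ci_upper))
    return RecoveryResult(n_screens, np.asarray(errors), np.asarray(covered))


def label_recovery(
    noise_sd: float, n_boot: int = 200, seed: int = 0
) -> tuple[int, int, pd.DataFrame]:
    """Run the canonical battery end to end and score label recovery.

    Returns (n_recovered, n_scenarios, per-scenario table); a ``no_hit``
    call counts as recovering an intended ``negative`` label.
    """
    cfg = default_config(noise_sd=noise_sd, n_boot=n_boot)
    bundle = run_pipeline(cfg, seed=seed)
    truth = bundle.truth.set_index("compound")["intended_label"]
    calls = (
        bundle.hit_calls.set_index("compound")["classification"]
        .map(lambda c: "negative" if c == "no_hit" else c)
    )
    table = pd.DataFrame({"intended": truth, "called": calls})
    table["recovered"] = table["intended"] == table["called"]
    return int(table["recovered"].sum()), len(table), table.reset_index()
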