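"""Response-level simulation studies: effect recovery, coverage, type-I error.

These studies exercise the mixed-model machinery directly at the response
level (daily log home range values drawn from the model that the analysis
assumes), so hundreds of replicates run in seconds.  The full GPS-level
simulator in :mod:`grazekit.simulate` covers the end-to-end path; these
helpers isolate the statistical properties of the association stage.

The default scenario mirrors the herd design the package targets: ~300 cows
in 14 mobs with repeated daily measurements nested in cow, a variant-presence
effect on daily log home range, and variance components of the magnitude seen
in herd data (between-mob and between-cow spread comparable to the residual).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import fit_lmm


@dataclasses.dataclass
class PanelScenario:
    """A cows-in-mobs repeated-measures design with one binary predictor."""

    n_cows: int = 300
    n_mobs: int = 14
    days: int = 10
    effect: float = 0.2          # variant-presence effect on the log response
    carrier_freq: float = 0.5
    intercept: float = 2.0       # log(hr_mcp) baseline, ~7.4 ha/d
    sd_mob: float = 0.3
    sd_cow: float = 0.3
    sd_resid: float = 0.5


def simulate_panel(sc: PanelScenario, seed: int) -> pd.DataFrame:
    """One realisation of the scenario: daily responses with known truth."""
    rng = np.random.default_rng(seed)
    mob_of_cow = rng.integers(0, sc.n_mobs, sc.n_cows)
    carrier = rng.random(sc.n_cows) < sc.carrier_freq
    u_mob = rng.normal(0, sc.sd_mob, sc.n_mobs)
    u_cow = rng.normal(0, sc.sd_cow, sc.n_cows)
    cow = np.repeat(np.arange(sc.n_cows), sc.days)
    y = (sc.intercept + sc.effect * carrier[cow]
         + u_mob[mob_of_cow[cow]] + u_cow[cow]
         + rng.normal(0, sc.sd_resid, len(cow)))
    return pd.DataFrame({
        "cow_id": cow, "mob": mob_of_cow[cow],
        "carrier": carrier[cow].astype(float), "y": y,
    })


def _fit_panel(panel: pd.DataFrame, reml: bool = True):
    X = np.column_stack([np.ones(len(panel)), panel["carrier"].to_numpy()])
    return fit_lmm(panel["y"].to_numpy(), X,
                   {"cow_id": panel["cow_id"].to_numpy(),
                    "mob": panel["mob"].to_numpy()},
                   reml=reml, xnames=["(Intercept)", "carrier"])


def coverage_study(sc: PanelScenario, n_reps: int, seed: int) -> dict:
    """95% Wald-Satterthwaite CI coverage of the true effect, plus estimates.

    Returns coverage percent, mean estimate, and the mean estimated
    between-mob variance component for recovery checks.
    """
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(n_reps) % (2**31)
    covered = 0
    est = np.empty(n_reps)
    vc_mob = np.empty(n_reps)
    c = np.array([0.0, 1.0])
    for i in range(n_reps):
        panel = simulate_panel(sc, int(child[i]))
        fit = _fit_panel(panel)
        b, se, df, _, _ = fit.contrast(c)
        half = stats.t.ppf(0.975, df) * se
        covered += (b - half <= sc.effect <= b + half)
        est[i] = b
        vc_mob[i] = fit.vc["mob"]
    return {
        "coverage_pct": 100.0 * covered / n_reps,
        "mean_estimate": float(est.mean()),
        "mean_vc_mob": float(vc_mob.mean()),
        "n_reps": n_reps,
    }


def type1_study(sc: PanelScenario, n_reps: int, seed: int,
                alpha: float = 0.05) -> dict:
    """Rejection rate of the variant test when the true effect is zero."""
    sc = dataclasses.replace(sc, effect=0.0)
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(n_reps) % (2**31)
    c = np.array([0.0, 1.0])
    rej = 0
    for i in range(n_reps):
        panel = simulate_panel(sc, int(child[i]))
        fit = _fit_panel(panel)
        _, _, _, _, p = fit.contrast(c)
        rej += p < alpha
    return {"rejection_rate": rej / n_reps, "n_reps": n_reps, "alpha": alpha}


def power_study(sc: PanelScenario, n_reps: int, seed: int,
                alpha: float = 0.05) -> dict:
    """Rejection rate at the scenario's (non-zero) effect size."""
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(n_reps) % (2**31)
    c = np.array([0.0, 1.0])
    rej = 0
    for i in range(n_reps):
        panel = simulate_panel(sc, int(child[i]))
        fit = _fit_panel(panel)
        _, _, _, _, p = fit.contrast(c)
        rej += p < alpha
    return {"rejection_rate": rej / n_reps, "n_reps": n_reps, "alpha": alpha}


def variance_recovery_study(n_reps: int, seed: int, n_mobs: int = 50,
                            cows_per_mob: int = 20, var_mob: float = 0.25,
                            var_resid: float = 1.0) -> dict:
    """Between-mob variance recovery on a one-level design (mob only).

    Simulates ``n_mobs`` groups of ``cows_per_mob`` observations with
    known variance components and reports the mean estimated sigma2_mob.
    """
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(n_reps) % (2**31)
    est = np.empty(n_reps)
    n = n_mobs * cows_per_mob
    mob = np.repeat(np.arange(n_mobs), cows_per_mob)
    X = np.ones((n, 1))
    for i in range(n_reps):
        rng = np.random.default_rng(int(child[i]))
        y = (rng.normal(0, np.sqrt(var_mob), n_mobs)[mob]
             + rng.normal(0, np.sqrt(var_resid), n))
        fit = fit_lmm(y, X, {"mob": mob}, reml=True, xnames=["(Intercept)"])
        est[i] = fit.vc["mob"]
    return {"mean_vc_mob": float(est.mean()), "true_vc_mob": var_mob,
            "n_reps": n_reps}
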