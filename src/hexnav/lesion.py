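"""Causal perturbations: Gaussian noise injected into analysis-layer units.

A lesion adds zero-mean Gaussian noise to the activations of targeted units
on every forward pass, with standard deviation ``noise_scale`` times the
maximum activation in the layer (per-pass by default).  The lesioned agent
is then evaluated greedily for a fixed number of test trials; performance is
the fraction of successful trials.  Noise of scale zero leaves behaviour
bit-identical to the unlesioned baseline under the same seeds, and the
perturbation is local: pre-noise activations of untouched units are exactly
those of the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dqn import NoiseLesion, QNetwork, evaluate


@dataclass
class LesionSpec:
    target_units: np.ndarray
    noise_scale: float
    n_test_trials: int = 25
    rng_seed: int = 0
    layer_max: float | None = None      # None -> per-forward-pass maximum

    def __post_init__(self):
        self.target_units = np.atleast_1d(np.asarray(self.target_units, dtype=int))
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be nonnegative")
        if len(self.target_units) == 0 and self.noise_scale > 0:
            raise ValueError("empty lesion target with positive noise")


@dataclass
class LesionResult:
    success_fraction: float
    steps: list
    baseline_success_fraction: float
    noise_scale: float
    target_units: np.ndarray


def run_lesion(net: QNetwork, env, spec: LesionSpec, phase: str = "train") -> LesionResult:
    """Evaluate the agent for ``n_test_trials`` greedy trials with the lesion
    active, alongside an unlesioned baseline under identical seeds."""
    baseline, _ = evaluate(net, env, spec.n_test_trials, spec.rng_seed, phase=phase)
    lesion = NoiseLesion(spec.target_units, spec.noise_scale,
                         np.random.default_rng(spec.rng_seed + 997),
                         layer_max=spec.layer_max)
    frac, steps = evaluate(net, env, spec.n_test_trials, spec.rng_seed,
                           lesion=lesion, phase=phase)
    return LesionResult(frac, steps, baseline, spec.noise_scale, spec.target_units)


def run_single_unit_lesions(net, env, units, noise_scale, n_test_trials=25,
                            rng_seed=0, phase="train") -> pd.DataFrame:
    """Sweep one unit at a time, a fixed noise level per unit."""
    rows = []
    for u in units:
        res = run_lesion(net, env, LesionSpec(np.array([u]), noise_scale,
                                              n_test_trials, rng_seed), phase=phase)
        rows.append({"unit": int(u), "noise_scale": noise_scale,
                     "success_fraction": res.success_fraction,
                     "baseline": res.baseline_success_fraction,
                     "n_trials": n_test_trials, "seed": rng_seed})
    return pd.DataFrame(rows)


def run_population_lesions(net, env, class_table: pd.DataFrame, noise_levels,
                           n_test_trials=25, rng_seed=0, phase="train") -> pd.DataFrame:
    """Lesion whole unit classes at each noise level; classes with zero
    members are marked absent (NaN success) rather than erroring."""
    rows = []
    for label, group in class_table.groupby("label"):
        units = group["unit"].to_numpy()
        for scale in noise_levels:
            if len(units) == 0:
                rows.append({"class_or_unit": label, "noise_scale": scale,
                             "success_fraction": np.nan, "n_units": 0,
                             "n_trials": n_test_trials, "seed": rng_seed})
                continue
            res = run_lesion(net, env, LesionSpec(units, scale, n_test_trials,
                                                  rng_seed), phase=phase)
            rows.append({"class_or_unit": label, "noise_scale": scale,
                         "success_fraction": res.success_fraction,
                         "n_units": len(units), "n_trials": n_test_trials,
                         "seed": rng_seed})
    return pd.DataFrame(rows)


def lesion_noise_curve(net, env, target_units, noise_levels, n_test_trials=25,
                       seeds=(0,), phase="train") -> pd.DataFrame:
    """Success fraction as a function of noise level, averaged over seeds
    (each seed fixes both the test trials and the noise draws)."""
    rows = []
    for seed in seeds:
        for scale in noise_levels:
            res = run_lesion(net, env, LesionSpec(np.asarray(target_units), scale,
                                                  n_test_trials, int(seed)),
                             phase=phase)
            rows.append({"noise_scale": scale, "seed": int(seed),
                         "success_fraction": res.success_fraction})
    return pd.DataFrame(rows)
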