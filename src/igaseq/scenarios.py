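"""Reference simulation scenarios used for validation and examples.

Each scenario builds a :class:`~igaseq.simulate.SimulationConfig` for a
designed experiment with known ground truth:

* ``study_shaped`` — the full cohort at the study's scale (575 taxa,
  16/15 subjects at age 2.5, 13/9 at age 5, mean depth 30,471, three
  fractions per subject) with the default group-level coating difference.
* ``targeting_recovery`` — the planted differential-targeting experiment:
  equal presort composition in both groups, background coating identical
  between groups and spread over (0.05, 0.95) so coating ranks are
  identifiable, and five planted taxa (presort abundance nearest 1%)
  with coating 0.1 in controls vs 0.8 in celiac progressors.
* ``mixing_null`` — complete sorting impurity (epsilon = 0.5) at depth
  1e5: sorting carries no signal and every ICI should sit near 1.
* ``calibration_null`` — no effect taxa and group-identical coating at
  reduced scale (S=50, 8 vs 8 subjects), for permutation-test
  calibration studies.
"""

from __future__ import annotations

import numpy as np

from .simulate import SimulationConfig, simulate_cohort


def study_shaped(seed: int = 0) -> SimulationConfig:
    """The cohort at full study scale with all defaults."""
    return SimulationConfig(seed=seed)


def mixing_null(seed: int = 0, n_taxa: int = 50,
                depth: float = 1e5) -> SimulationConfig:
    """Complete-mixing cohort: epsilon = 0.5, single age, 16/15 subjects."""
    return SimulationConfig(
        n_taxa=n_taxa, seed=seed, impurity=0.5, mean_depth=depth,
        group_sizes={2.5: {"control": 16, "celiac": 15}},
    )


def calibration_null(seed: int = 0, n_taxa: int = 50,
                     n_per_group: int = 8) -> SimulationConfig:
    """No-effect cohort at reduced scale for null calibration."""
    return SimulationConfig(
        n_taxa=n_taxa, seed=seed,
        group_sizes={2.5: {"control": n_per_group, "celiac": n_per_group}},
        coating_mean={"control": 0.0602, "celiac": 0.0602},
    )


def targeting_recovery(seed: int = 0, n_taxa: int = 100,
                       n_planted: int = 5,
                       theta_planted=(0.1, 0.8)):
    """Planted differential-targeting cohort with ground truth.

    Returns
    -------
    (cohort, truth, planted_taxa)
        ``planted_taxa`` is the list of taxon ids carrying the coating
        effect; all other taxa have group-identical composition and
        coating.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA11]))
    theta = rng.uniform(0.05, 0.95, n_taxa)
    shared = {"control": theta, "celiac": theta}
    # probe run: the composition substream depends only on (seed, n_taxa),
    # so a cheap draw reveals the base composition before the real run
    probe = SimulationConfig(
        n_taxa=n_taxa, seed=seed, mean_depth=100,
        group_sizes={2.5: {"control": 2, "celiac": 2}},
        coating_prob=shared,
    )
    _, probe_truth = simulate_cohort(probe)
    base = probe_truth.base_composition["control"].to_numpy()
    planted_idx = np.argsort(np.abs(base - 0.01))[:n_planted]
    config = SimulationConfig(
        n_taxa=n_taxa, seed=seed,
        group_sizes={2.5: {"control": 16, "celiac": 15}},
        coating_prob=shared,
        coating_effects={int(i): tuple(theta_planted) for i in planted_idx},
    )
    cohort, truth = simulate_cohort(config)
    planted_taxa = [truth.base_composition.index[i] for i in planted_idx]
    return cohort, truth, planted_taxa
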