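"""Forward simulation of IgA-seq cohorts with full ground truth.

The generative model mirrors the sorting experiment end to end:

1. Each group (control / celiac) has a latent community composition ``p``
   over ``S`` taxa; planted effect taxa shift the celiac composition by a
   log2 fold-change. Subjects draw their personal composition from a
   Dirichlet centered on the group composition.
2. Each taxon ``t`` in group ``g`` has a latent IgA coating probability
   ``theta[t, g]`` — the chance a cell of that taxon is antibody-coated.
   Subjects draw a personal coating vector from a Beta with mean ``theta``
   and concentration ``kappa`` (subject-level overdispersion).
3. Magnetic sorting splits cells into an IgA+ capture and an IgA-
   flow-through with symmetric cross-contamination ``epsilon``: a coated
   cell ends up in the IgA- fraction (and vice versa) with probability
   ``epsilon``. The expected fraction compositions are

       q_pos[t] ∝ (1 - eps) * p[t] * th[t] + eps * p[t] * (1 - th[t])
       q_neg[t] ∝ (1 - eps) * p[t] * (1 - th[t]) + eps * p[t] * th[t]

   At ``eps = 0`` these reduce to ``q_pos ∝ p*th`` and ``q_neg ∝ p*(1-th)``;
   at ``eps = 0.5`` sorting is uninformative and both equal ``p``.
4. Sequencing draws a multinomial of log-normally distributed depth
   (mean 30,471 reads — the cohort's mean) from each fraction's
   composition: presort from ``p``, sorted fractions from ``q_pos``/``q_neg``.

The flow-cytometry IgA+ fraction of a subject is ``sum_t p[t]*th[t]``.

Randomness flows from a single root seed through named substreams
(NumPy ``SeedSequence``/PCG64, which is stable across platforms), so each
stage is individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .datatypes import Cohort, CountTable, FeatureTable, SampleMetadata
from .errors import ParameterError

# Substream order is part of the reproducibility contract.
_STREAMS = ("composition", "coating", "depth", "counts", "flow", "features")

#: Cohort sizes of the study: subjects per (age, group).
DEFAULT_GROUP_SIZES = {
    2.5: {"control": 16, "celiac": 15},
    5.0: {"control": 13, "celiac": 9},
}

#: Group-mean coating probabilities; the study's flow-cytometry IgA+
#: fractions (6.02% controls, 12.8% celiac progressors).
DEFAULT_COATING_MEAN = {"control": 0.0602, "celiac": 0.128}

DEFAULT_MEAN_DEPTH = 30471.0


@dataclass
class SimulationConfig:
    """Parameters of the cohort generator.

    Attributes
    ----------
    n_taxa:
        Community size ``S`` (the study resolved 575 ASVs).
    group_sizes:
        Subjects per age per group; defaults to the study's 16/15 at age
        2.5 and 13/9 at age 5.
    base_abundance_model:
        ``"lognormal"`` (default) draws taxon base abundances from a
        log-normal with ``base_lognormal_sigma``; ``"dirichlet"`` draws
        from a symmetric Dirichlet with ``base_dirichlet_alpha``.
    effect_taxa:
        Map taxon index -> log2 fold-change applied to the celiac presort
        composition (renormalized).
    coating_mean:
        Per-group mean coating probability across taxa.
    coating_concentration:
        Beta concentration of the across-taxon coating distribution
        (small values give a long tail of strongly coated taxa).
    coating_effects:
        Map taxon index -> (theta_control, theta_celiac) overrides for
        planted differential-targeting taxa.
    coating_kappa:
        Subject-level Beta overdispersion concentration.
    impurity:
        Sorting cross-contamination ``epsilon`` in [0, 0.5].
    mean_depth, depth_cv:
        Log-normal read-depth model (mean reads per sample, coefficient
        of variation).
    subject_concentration:
        Dirichlet concentration of subject compositions around the group
        composition.
    seed:
        Root seed for all substreams.
    """

    n_taxa: int = 575
    group_sizes: Mapping[float, Mapping[str, int]] = field(
        default_factory=lambda: {a: dict(g) for a, g in DEFAULT_GROUP_SIZES.items()}
    )
    base_abundance_model: str = "lognormal"
    base_lognormal_sigma: float = 1.5
    base_dirichlet_alpha: float = 0.5
    effect_taxa: Mapping[int, float] = field(default_factory=dict)
    coating_mean: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COATING_MEAN)
    )
    coating_prob: Optional[Mapping[str, np.ndarray]] = None
    coating_effects: Mapping[int, tuple] = field(default_factory=dict)
    coating_concentration: float = 2.0
    coating_kappa: float = 50.0
    impurity: float = 0.05
    mean_depth: float = DEFAULT_MEAN_DEPTH
    depth_cv: float = 0.3
    subject_concentration: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 1:
            raise ParameterError(f"n_taxa must be >= 1, got {self.n_taxa}")
        if not (0.0 <= self.impurity <= 0.5):
            raise ParameterError(
                f"impurity must lie in [0, 0.5], got {self.impurity}"
            )
        if self.mean_depth < 1:
            raise ParameterError("mean_depth must be >= 1")
        for par in ("base_lognormal_sigma", "base_dirichlet_alpha",
                    "coating_concentration", "coating_kappa",
                    "subject_concentration"):
            if getattr(self, par) <= 0:
                raise ParameterError(f"{par} must be > 0")
        for g, m in self.coating_mean.items():
            if not (0.0 < m < 1.0):
                raise ParameterError(
                    f"coating_mean[{g!r}] must lie in (0, 1), got {m}"
                )
        if self.coating_prob is not None:
            for g, th in self.coating_prob.items():
                th = np.asarray(th, dtype=float)
                if th.shape != (self.n_taxa,):
                    raise ParameterError(
                        f"coating_prob[{g!r}] must have shape ({self.n_taxa},)"
                    )
                if not ((th > 0) & (th < 1)).all():
                    raise ParameterError(
                        f"coating_prob[{g!r}] must lie strictly in (0, 1)"
                    )
        for t, pair in self.coating_effects.items():
            lo, hi = float(pair[0]), float(pair[1])
            if not (0 < lo < 1 and 0 < hi < 1):
                raise ParameterError(
                    f"coating_effects[{t}] must lie strictly in (0, 1)"
                )
        self.group_sizes = {
            float(a): dict(g) for a, g in self.group_sizes.items()
        }


@dataclass
class SortedCohortTruth:
    """Ground truth emitted alongside a simulated cohort.

    Per-subject quantities are keyed by the subject's presort sample id.
    """

    config: SimulationConfig
    base_composition: pd.DataFrame        # taxa x groups
    coating_prob: pd.DataFrame            # taxa x groups (latent theta)
    presort_composition: pd.DataFrame     # taxa x presort sample ids (p)
    realized_coating: pd.DataFrame        # taxa x presort sample ids (theta~)
    expected_igapos: pd.DataFrame         # taxa x presort sample ids (q+)
    expected_iganeg: pd.DataFrame         # taxa x presort sample ids (q-)
    flow_fraction: pd.Series              # presort sample id -> sum p*theta~
    cohort: Cohort


def _streams(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss)
            for name, ss in zip(_STREAMS, children)}


def expected_sorted_compositions(p, theta, epsilon):
    """Expected IgA+ / IgA- compositions after an impure sort.

    Parameters
    ----------
    p : array
        Presort composition, must sum to 1 within 1e-9.
    theta : array
        Per-taxon coating probabilities in (0, 1).
    epsilon : float
        Symmetric cross-contamination in [0, 0.5].

    Returns
    -------
    (q_pos, q_neg) : two arrays, each summing to 1.
    """
    p = np.asarray(p, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if p.shape != theta.shape:
        raise ParameterError("p and theta must have the same shape")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ParameterError(
            f"p must sum to 1 within 1e-9 (got sum {p.sum()!r})"
        )
    if not ((theta > 0) & (theta < 1)).all():
        raise ParameterError("theta must lie strictly in (0, 1)")
    if not (0.0 <= epsilon <= 0.5):
        raise ParameterError("epsilon must lie in [0, 0.5]")
    coated = p * theta
    uncoated = p * (1.0 - theta)
    q_pos = (1.0 - epsilon) * coated + epsilon * uncoated
    q_neg = (1.0 - epsilon) * uncoated + epsilon * coated
    return q_pos / q_pos.sum(), q_neg / q_neg.sum()


def _base_compositions(config: SimulationConfig, rng) -> pd.DataFrame:
    S = config.n_taxa
    taxa = [f"ASV{i + 1:04d}" for i in range(S)]
    if config.base_abundance_model == "lognormal":
        raw = rng.lognormal(mean=0.0, sigma=config.base_lognormal_sigma, size=S)
    elif config.base_abundance_model == "dirichlet":
        raw = rng.dirichlet(np.full(S, config.base_dirichlet_alpha))
    else:
        raise ParameterError(
            f"unknown base_abundance_model {config.base_abundance_model!r}"
        )
    control = raw / raw.sum()
    celiac = control.copy()
    for t, log2fc in config.effect_taxa.items():
        celiac[int(t)] *= 2.0 ** float(log2fc)
    celiac = celiac / celiac.sum()
    return pd.DataFrame({"control": control, "celiac": celiac}, index=taxa)


def _coating_probs(config: SimulationConfig, taxa, rng) -> pd.DataFrame:
    S = config.n_taxa
    if config.coating_prob is not None:
        # copy: groups may share one input array and effects are per-group
        theta = {g: np.array(config.coating_prob[g], dtype=float, copy=True)
                 for g in ("control", "celiac")}
    else:
        c = config.coating_concentration
        m_ctrl = config.coating_mean["control"]
        m_cel = config.coating_mean["celiac"]
        th_ctrl = rng.beta(m_ctrl * c, (1.0 - m_ctrl) * c, size=S)
        th_ctrl = np.clip(th_ctrl, 1e-4, 1.0 - 1e-4)
        # shift the same taxon-level propensity on the logit scale so the
        # two groups' coating profiles stay correlated across taxa
        shift = logit(m_cel) - logit(m_ctrl)
        th_cel = expit(logit(th_ctrl) + shift)
        theta = {"control": th_ctrl, "celiac": th_cel}
    for t, (lo, hi) in config.coating_effects.items():
        theta["control"][int(t)] = float(lo)
        theta["celiac"][int(t)] = float(hi)
    theta = {g: np.clip(v, 1e-4, 1.0 - 1e-4) for g, v in theta.items()}
    return pd.DataFrame(theta, index=taxa)


def _draw_depth(config: SimulationConfig, rng) -> int:
    cv = config.depth_cv
    if cv <= 0:
        return max(1, int(round(config.mean_depth)))
    sigma2 = np.log1p(cv * cv)
    mu = np.log(config.mean_depth) - sigma2 / 2.0
    return max(1, int(round(rng.lognormal(mean=mu, sigma=np.sqrt(sigma2)))))


def simulate_cohort(config: SimulationConfig):
    """Simulate a full sorted cohort.

    Returns
    -------
    (cohort, truth) : (:class:`Cohort`, :class:`SortedCohortTruth`)
        One presort + one igapos + one iganeg sample per subject per age;
        identical seeds give identical output.
    """
    rngs = _streams(config.seed)
    base = _base_compositions(config, rngs["composition"])
    taxa = base.index
    theta_group = _coating_probs(config, taxa, rngs["coating"])

    # persistent subject roster: a subject present at several ages keeps its id
    roster = {}
    for group in ("control", "celiac"):
        n_max = max(sizes.get(group, 0) for sizes in config.group_sizes.values())
        prefix = "C" if group == "control" else "P"
        roster[group] = [f"{prefix}{i + 1:02d}" for i in range(n_max)]

    meta_rows = []
    count_cols = {}
    truth_p, truth_th, truth_qp, truth_qn, flow = {}, {}, {}, {}, {}

    for age in sorted(config.group_sizes):
        for group in ("control", "celiac"):
            n = config.group_sizes[age].get(group, 0)
            p_group = base[group].to_numpy()
            th_group = theta_group[group].to_numpy()
            for subject in roster[group][:n]:
                alpha = np.maximum(p_group * config.subject_concentration, 1e-8)
                p_subj = rngs["composition"].dirichlet(alpha)
                if p_subj.sum() <= 0:   # pathological alpha underflow
                    p_subj = p_group.copy()
                p_subj = p_subj / p_subj.sum()
                kappa = config.coating_kappa
                th_subj = rngs["coating"].beta(
                    th_group * kappa, (1.0 - th_group) * kappa
                )
                th_subj = np.clip(th_subj, 1e-6, 1.0 - 1e-6)
                q_pos, q_neg = expected_sorted_compositions(
                    p_subj, th_subj, config.impurity
                )
                compositions = {
                    "presort": p_subj, "igapos": q_pos, "iganeg": q_neg,
                }
                presort_id = None
                for fraction in ("presort", "igapos", "iganeg"):
                    sid = f"{subject}_a{age:g}_{fraction}"
                    depth = _draw_depth(config, rngs["depth"])
                    count_cols[sid] = rngs["counts"].multinomial(
                        depth, compositions[fraction]
                    )
                    meta_rows.append(
                        dict(sample_id=sid, subject_id=subject, group=group,
                             age=age, fraction=fraction)
                    )
                    if fraction == "presort":
                        presort_id = sid
                truth_p[presort_id] = p_subj
                truth_th[presort_id] = th_subj
                truth_qp[presort_id] = q_pos
                truth_qn[presort_id] = q_neg
                flow[presort_id] = float(np.dot(p_subj, th_subj))

    counts = pd.DataFrame(count_cols, index=taxa).astype(np.int64)
    cohort = Cohort(CountTable(counts), SampleMetadata(pd.DataFrame(meta_rows)))
    truth = SortedCohortTruth(
        config=config,
        base_composition=base,
        coating_prob=theta_group,
        presort_composition=pd.DataFrame(truth_p, index=taxa),
        realized_coating=pd.DataFrame(truth_th, index=taxa),
        expected_igapos=pd.DataFrame(truth_qp, index=taxa),
        expected_iganeg=pd.DataFrame(truth_qn, index=taxa),
        flow_fraction=pd.Series(flow),
        cohort=cohort,
    )
    return cohort, truth


def simulate_flow_fractions(truth: SortedCohortTruth,
                            noise_concentration: Optional[float] = None,
                            seed: Optional[int] = None) -> pd.Series:
    """Per-subject IgA+ flow-cytometry fraction, ``sum_t p[t] * theta~[t]``.

    With ``noise_concentration`` set, a Beta measurement error with that
    concentration is layered on top (seeded).
    """
    fractions = truth.flow_fraction.copy()
    if noise_concentration is None:
        return fractions
    if noise_concentration <= 0:
        raise ParameterError("noise_concentration must be > 0")
    root = truth.config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(root).spawn(
        len(_STREAMS))[_STREAMS.index("flow")])
    c = noise_concentration
    noisy = rng.beta(fractions.to_numpy() * c,
                     (1.0 - fractions.to_numpy()) * c)
    return pd.Series(noisy, index=fractions.index)


def simulate_feature_table(n_features: int,
                           n_per_group=(9, 7),
                           effect_features: Optional[Mapping[int, float]] = None,
                           noise_sd: float = 0.5,
                           seed: int = 0):
    """Simulate a plasma-analyte screen (metabolites / cytokines).

    Features are log-normal; each effect feature's celiac mean is shifted
    by its log2 fold-change. ``n_per_group`` is (controls, celiac) — the
    study's plasma cohort was 9 controls vs 7 progressors.

    Returns
    -------
    (features, groups, truth)
        A :class:`FeatureTable`, a Series of group labels per sample, and
        a truth DataFrame with each feature's planted log2 fold-change.
    """
    if n_features < 1:
        raise ParameterError("n_features must be >= 1")
    effect_features = dict(effect_features or {})
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(
        len(_STREAMS))[_STREAMS.index("features")])
    n_ctrl, n_cel = int(n_per_group[0]), int(n_per_group[1])
    feature_ids = [f"feat{i + 1:03d}" for i in range(n_features)]
    sample_ids = ([f"ctrl{i + 1:02d}" for i in range(n_ctrl)]
                  + [f"cd{i + 1:02d}" for i in range(n_cel)])
    groups = pd.Series(["control"] * n_ctrl + ["celiac"] * n_cel,
                       index=sample_ids, name="group")
    log_base = rng.normal(0.0, 1.0, size=n_features)
    log2fc = np.zeros(n_features)
    for idx, fc in effect_features.items():
        log2fc[int(idx)] = float(fc)
    mu = log_base[:, None] + np.where(
        groups.to_numpy() == "celiac", 1.0, 0.0
    )[None, :] * (log2fc[:, None] * np.log(2.0))
    values = np.exp(mu + rng.normal(0.0, noise_sd, size=mu.shape))
    features = FeatureTable(
        pd.DataFrame(values, index=feature_ids, columns=sample_ids)
    )
    truth = pd.DataFrame({"log2fc": log2fc}, index=feature_ids)
    return features, groups, truth


def write_truth(truth: SortedCohortTruth, path) -> None:
    """Write the taxon-level ground truth (theta per group, presort log2fc)."""
    cfg = truth.config
    delta = pd.Series(0.0, index=truth.base_composition.index)
    for t, fc in cfg.effect_taxa.items():
        delta.iloc[int(t)] = float(fc)
    rows = []
    for group in ("control", "celiac"):
        rows.append(pd.DataFrame({
            "taxon_id": truth.base_composition.index,
            "group": group,
            "base_abundance": truth.base_composition[group].to_numpy(),
            "coating_prob": truth.coating_prob[group].to_numpy(),
            "presort_log2fc": delta.to_numpy(),
        }))
    pd.concat(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
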