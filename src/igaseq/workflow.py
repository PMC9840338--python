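"""End-to-end orchestration: one config object, one analyze() call, one
report bundle.

``analyze`` wires the full pipeline over a sorted cohort — per-age ICI
tables and heatmap matrices, differential-abundance screens per fraction,
the composite differential-targeting call, and the community statistics —
and returns the results as named DataFrames. ``write_bundle`` serializes
them as TSV files whose leading ``#`` provenance lines echo every
threshold, the pseudocount, the seed, the test engine, and a hash of the
configuration, so a report is interpretable (and reproducible) on its own.
All serialization is deterministic: identical config + inputs give
byte-identical files.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .datatypes import Cohort
from .errors import ParameterError
from .diversity import (
    bray_curtis_matrix,
    observed_richness,
    pca,
    permanova,
)
from .ici import compute_ici_table, heatmap_matrix
from .screens import differential_abundance, differential_targeting

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """All knobs of an end-to-end run, with the pipeline defaults."""

    q_max: float = 0.05
    p_max: float = 0.01
    comparability_q_floor: float = 0.05
    high_coater_threshold: float = 10.0
    pseudocount: float = 1.0
    n_perm: int = 999
    min_mean_abundance: float = 0.01
    volcano_fc_threshold: float = 1.2
    volcano_neglog10_p_threshold: float = 0.1
    ici_aggregation: str = "mean"
    coating_on: str = "igapos"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("q_max", "p_max", "comparability_q_floor"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ParameterError(f"{name} must lie in (0, 1], got {v}")
        if self.pseudocount < 0:
            raise ParameterError("pseudocount must be >= 0")
        if self.n_perm < 1:
            raise ParameterError("n_perm must be >= 1")
        if self.high_coater_threshold <= 0:
            raise ParameterError("high_coater_threshold must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ParameterError(f"unknown config fields: {sorted(unknown)}")
        return cls(**known)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ReportBundle:
    """Named result tables plus the provenance that produced them."""

    tables: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def _age_tag(age: float) -> str:
    return format(float(age), "g").replace(".", "p")


def analyze(cohort: Cohort, config: RunConfig | None = None) -> ReportBundle:
    """Run the full pipeline on a sorted cohort."""
    config = config or RunConfig()
    meta = cohort.metadata.table
    ages = sorted(meta["age"].unique())
    bundle = ReportBundle(provenance={
        "version": __version__,
        "config_hash": config.config_hash(),
        "test_engine": "two-group |mean difference| permutation "
                       "(exhaustive <= 20000 arrangements, else sampled "
                       "with the +1/(B+1) convention); replaces the "
                       "negative-binomial quasi-likelihood F test",
        **{k: v for k, v in config.to_dict().items()},
    })
    tables = bundle.tables

    for age in ages:
        tag = _age_tag(age)
        has_sorted = bool(cohort.metadata.select_ids(fraction="igapos",
                                                     age=age))
        if has_sorted:
            ici_table = compute_ici_table(
                cohort, age, aggregation=config.ici_aggregation,
                pseudocount=config.pseudocount,
                high_coater_threshold=config.high_coater_threshold)
            tables[f"ici_age{tag}"] = ici_table
            tables[f"heatmap_age{tag}"] = heatmap_matrix(ici_table)

        fractions = ["presort"] + (["igapos", "iganeg"] if has_sorted else [])
        for fraction in fractions:
            res = differential_abundance(
                cohort, fraction, age, q_max=config.q_max,
                p_max=config.p_max, pseudocount=config.pseudocount,
                n_perm=config.n_perm, seed=config.seed)
            tables[f"differential_{fraction}_age{tag}"] = res.table

        if has_sorted:
            call = differential_targeting(
                cohort, age,
                comparability_q_floor=config.comparability_q_floor,
                coating_on=config.coating_on, q_max=config.q_max,
                p_max=config.p_max, pseudocount=config.pseudocount,
                n_perm=config.n_perm, seed=config.seed)
            tables[f"targeting_age{tag}"] = call.table

        presort = cohort.select(fraction="presort", age=age)
        groups = cohort.metadata.groups_of(presort.sample_ids)
        dm = bray_curtis_matrix(presort)
        perm = permanova(dm, groups.to_numpy(), n_perm=config.n_perm,
                         seed=config.seed)
        tables[f"permanova_age{tag}"] = pd.DataFrame(
            [{"pseudo_F": perm.pseudo_F, "R2": perm.R2,
              "p_value": perm.p_value,
              "n_permutations": perm.n_permutations, "mode": perm.mode}])
        from .ici import relative_abundance
        rel = relative_abundance(presort, pseudocount=0.0).proportions
        coords, evr = pca(rel, n_components=min(2, presort.n_samples - 1,
                                                presort.n_taxa))
        coords = coords.copy()
        coords["group"] = groups.values
        coords.index.name = "sample_id"
        tables[f"pca_age{tag}"] = coords
        bundle.provenance[f"pca_age{tag}_explained"] = ",".join(
            format(v, ".6g") for v in evr)

    alpha = observed_richness(cohort.counts).rename("observed_richness")
    alpha_df = meta.set_index("sample_id").join(alpha)
    tables["alpha_diversity"] = alpha_df.reset_index()
    return bundle


def write_bundle(bundle: ReportBundle, outdir) -> list:
    """Write every table as a provenance-headed TSV; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = "".join(
        f"# {key}={value}\n" for key, value in sorted(
            bundle.provenance.items(), key=lambda kv: str(kv[0]))
    )
    paths = []
    for name in sorted(bundle.tables):
        df = bundle.tables[name]
        buf = _io.StringIO()
        index = df.index.name is not None or not isinstance(
            df.index, pd.RangeIndex)
        if index:
            df = df.rename_axis(df.index.name or "id")
        df.to_csv(buf, sep="\t", float_format=_FLOAT_FMT, index=index)
        path = outdir / f"{name}.tsv"
        path.write_text(header + buf.getvalue(), encoding="utf-8")
        paths.append(path)
    return paths


def read_bundle_table(path) -> pd.DataFrame:
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    return pd.read_csv(_io.StringIO("".join(lines)), sep="\t")


def report(outdir) -> str:
    """Human-readable tallies from a written bundle (markdown text).

    Counts significant taxa per fraction/age, high coaters per group, and
    differentially targeted taxa — the headline-style summary of a run.
    """
    outdir = Path(outdir)
    expected_kinds = ("differential_", "targeting_", "ici_")
    files = sorted(outdir.glob("*.tsv"))
    if not files:
        raise FileNotFoundError(
            f"no report tables under {outdir}; expected TSVs named "
            f"{', '.join(k + '*' for k in expected_kinds)} and diversity "
            "summaries")
    lines = ["# IgA-seq analysis summary", ""]
    for path in files:
        name = path.stem
        df = read_bundle_table(path)
        if name.startswith("differential_"):
            n_sig = int(df["significant"].sum())
            lines.append(f"- {name}: {n_sig} significant taxa "
                         f"of {len(df)}")
        elif name.startswith("targeting_"):
            n = int(df["differentially_targeted"].sum())
            lines.append(f"- {name}: {n} differentially targeted taxa")
        elif name.startswith("ici_"):
            hc_c = int(df["high_coater_control"].sum())
            hc_e = int(df["high_coater_celiac"].sum())
            n_ret = int(df["retained"].sum())
            lines.append(
                f"- {name}: {hc_c} high coaters (control), "
                f"{hc_e} high coaters (celiac), {n_ret} taxa retained "
                "for the heatmap")
        elif name.startswith("permanova_"):
            row = df.iloc[0]
            lines.append(
                f"- {name}: pseudo-F={row['pseudo_F']:.4g}, "
                f"p={row['p_value']:.4g}")
        elif name == "alpha_diversity":
            mean_rich = df["observed_richness"].mean()
            lines.append(
                f"- alpha_diversity: mean observed richness "
                f"{mean_rich:.1f} over {len(df)} samples")
    return "\n".join(lines) + "\n"
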