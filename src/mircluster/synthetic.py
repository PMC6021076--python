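"""Synthetic qPCR cohorts with the correlation structure the analysis assumes.

The generator emulates a matched term/preterm plasma miRNA panel study:
42 samples (21 matched pairs), ~58 detected miRNAs in three genomic
clusters (a large chr14 imprinted cluster, a chr19 imprinted cluster, and
the miR-17/92 family split across chr13 and chrX), within-cluster positive
co-expression driven by per-cluster latent factors, negative coupling
between the chr14 and chr19 clusters that is stronger in preterm samples,
qPCR censoring of late-amplifying reactions, and birth outcomes linked to
the cluster factors.

Per sample ``s`` in group ``g`` and miRNA ``m`` of cluster ``c``::

    −∆CT[s, m] = λ_m · a_g(c) · f_c(s) + ε,   ε ~ N(0, noise_sd²)
    CT[s, m]   = base_m − (−∆CT[s, m])        (censored where CT > censor_ct)

with latent factors ``f(s) ~ MVN(0, factor_corr[g])`` and group-specific
loading attenuation ``a_g(c)``. Gestational age is a linear function of the
latent factors (or, optionally, of the observable row-mean cluster scores)
plus noise; samples are rejection-sampled until each group (label by the
37-week threshold) reaches the target count, then paired in order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import LocusLabel
from .io_types import (
    PTB,
    TERM,
    CtMatrix,
    MirnaAnnotation,
    SampleMetadata,
    ValidationError,
    write_annotations_gff3,
    write_ct_matrix,
    write_metadata,
)


@dataclass(frozen=True)
class ClusterLocus:
    """One simulated genomic locus: n miRNAs evenly spaced on a chromosome."""

    name: str
    n_mirnas: int
    chromosome: str
    base_position: int
    spacing_bp: int
    family: str | None = None


@dataclass
class SimulationConfig:
    """Parameters of the simulated cohort (defaults emulate the study design:
    21 matched pairs, clusters of 33/15/10 miRNAs, preterm = ≤37 weeks)."""

    n_pairs: int = 21
    clusters: list[ClusterLocus] = field(
        default_factory=lambda: [
            ClusterLocus("c14mc", 33, "chr14", 101_300_000, 1500),
            ClusterLocus("c19mc", 15, "chr19", 53_700_000, 2000),
            ClusterLocus("miR-17/92", 6, "chr13", 91_350_000, 600, family="miR-17/92"),
            ClusterLocus("miR-17/92", 4, "chrX", 134_170_000, 700, family="miR-17/92"),
        ]
    )
    loading_mean: float = 0.8
    loading_sd: float = 0.05
    #: group → cluster → multiplicative loading attenuation (within-cluster
    #: coupling differences; the chr14 cluster decoheres in preterm samples,
    #: the chr19 cluster tightens).
    loading_scale: dict = field(
        default_factory=lambda: {
            TERM: {},
            PTB: {"c14mc": 0.75, "c19mc": 1.1},
        }
    )
    #: group → latent factor correlation matrix, cluster order as below.
    factor_corr: dict = field(
        default_factory=lambda: {
            TERM: [[1.0, -0.3, 0.2], [-0.3, 1.0, -0.2], [0.2, -0.2, 1.0]],
            PTB: [[1.0, -0.7, 0.4], [-0.7, 1.0, -0.2], [0.4, -0.2, 1.0]],
        }
    )
    noise_sd: float = 0.4
    ct_base_mean: float = 42.0
    ct_base_sd: float = 4.0
    censor_ct: float = 50.0
    #: cluster → effect on gestational age, weeks per unit factor (or score).
    outcome_betas: dict = field(
        default_factory=lambda: {"c14mc": 0.8, "c19mc": -0.6, "miR-17/92": 0.0}
    )
    outcome_on: str = "factor"  # "factor" | "score"
    outcome_noise_sd: float = 0.9
    ga_intercept: float = 37.5
    ptb_cutoff: float = 37.0
    #: birth weight: grams at 37.5 weeks, grams per week, residual sd.
    bw_intercept: float = 2850.0
    bw_per_week: float = 160.0
    bw_noise_sd: float = 250.0
    #: head circumference: cm at 37.5 weeks, cm per week, cm per unit of the
    #: chr19 factor, residual sd.
    hc_intercept: float = 32.6
    hc_per_week: float = 0.3
    hc_c19_beta: float = -0.4
    hc_noise_sd: float = 1.0
    seed: int = 0

    def cluster_names(self) -> list[str]:
        names = []
        for c in self.clusters:
            if c.name not in names:
                names.append(c.name)
        return names

    def validate(self) -> None:
        for c in self.clusters:
            if c.spacing_bp > 10_000:
                raise ValidationError(
                    f"{c.name}: spacing {c.spacing_bp} bp > 10 kb breaks chaining"
                )
        names = self.cluster_names()
        sizes: dict[str, int] = {}
        for c in self.clusters:
            sizes[c.name] = sizes.get(c.name, 0) + c.n_mirnas
        for name, n in sizes.items():
            if n < 2:
                raise ValidationError(f"cluster {name} has {n} miRNA(s); need >= 2")
        k = len(names)
        for group, mat in self.factor_corr.items():
            m = np.asarray(mat, dtype=float)
            if m.shape != (k, k):
                raise ValidationError(
                    f"factor_corr[{group}] has shape {m.shape}, expected {(k, k)}"
                )
            if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 1.0):
                raise ValidationError(
                    f"factor_corr[{group}] must be symmetric with unit diagonal"
                )
            if np.linalg.eigvalsh(m).min() < -1e-10:
                raise ValidationError(f"factor_corr[{group}] is not PSD")
        if self.outcome_on not in ("factor", "score"):
            raise ValidationError(f"unknown outcome_on {self.outcome_on!r}")


@dataclass
class SimulationTruth:
    """Ground truth of a simulated cohort, sufficient to recompute every
    generated −∆CT given the recorded noise draws (seeded)."""

    factors: pd.DataFrame  # samples × clusters, latent scores
    loadings: pd.Series  # per-miRNA base loading λ_m
    ct_base: pd.Series  # per-miRNA baseline CT
    cluster_of: dict  # mirna_id → cluster name
    group_of: dict  # sample_id → term/PTB
    dct: pd.DataFrame  # generated −∆CT before censoring
    censored: pd.DataFrame  # boolean mask of censored cells
    scores_used: pd.DataFrame | None  # observable scores, when outcome_on="score"
    outcome_betas: dict
    outcome_on: str
    config: SimulationConfig

    def to_json(self, path: str | Path) -> None:
        payload = {
            "factors": self.factors.to_dict(),
            "loadings": self.loadings.to_dict(),
            "ct_base": self.ct_base.to_dict(),
            "cluster_of": self.cluster_of,
            "group_of": self.group_of,
            "outcome_betas": self.outcome_betas,
            "outcome_on": self.outcome_on,
            "config": _config_dict(self.config),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["clusters"] = [asdict(c) if not isinstance(c, dict) else c for c in config.clusters]
    return d


def paper_default_config(seed: int = 0) -> SimulationConfig:
    """The documented default cohort: 21 matched pairs and 58 miRNAs in
    clusters of 33 (chr14), 15 (chr19) and 10 (miR-17/92, split chr13/chrX),
    with outcome dispersion giving an overall gestational-age sd near 1.6
    weeks."""
    return SimulationConfig(seed=seed)


def _mirna_ids(config: SimulationConfig) -> tuple[list[str], list[MirnaAnnotation], dict]:
    ids: list[str] = []
    annotations: list[MirnaAnnotation] = []
    cluster_of: dict[str, str] = {}
    for locus in config.clusters:
        tag = locus.name.replace("miR-17/92", "mir1792").replace("/", "-")
        chrom_tag = locus.chromosome.removeprefix("chr")
        for k in range(locus.n_mirnas):
            mid = f"sim-{tag}-{chrom_tag}-{k + 1:02d}"
            start = locus.base_position + k * locus.spacing_bp
            ids.append(mid)
            annotations.append(
                MirnaAnnotation(
                    mirna_id=mid,
                    chromosome=locus.chromosome,
                    start=start,
                    end=start + 80,
                    strand="+",
                    family=locus.family,
                )
            )
            cluster_of[mid] = locus.name
    return ids, annotations, cluster_of


def locus_labels(config: SimulationConfig) -> list[LocusLabel]:
    """Cytoband-style span labels for the purely genomic clusters (the
    family clusters are already named through their family label)."""
    labels = []
    for locus in config.clusters:
        if locus.family is None:
            span = locus.n_mirnas * locus.spacing_bp + 200
            labels.append(
                LocusLabel(
                    chromosome=locus.chromosome,
                    start=locus.base_position - 100,
                    end=locus.base_position + span,
                    name=locus.name,
                )
            )
    return labels


def family_table(config: SimulationConfig) -> dict[str, str]:
    _, annotations, _ = _mirna_ids(config)
    return {a.mirna_id: a.family for a in annotations if a.family}


def simulate_cohort(
    config: SimulationConfig | None = None,
) -> tuple[CtMatrix, list[MirnaAnnotation], SampleMetadata, SimulationTruth]:
    """Simulate one matched term/PTB cohort under the configured model."""
    config = config or paper_default_config()
    config.validate()
    rng = np.random.default_rng(config.seed)

    mirna_ids, annotations, cluster_of = _mirna_ids(config)
    names = config.cluster_names()
    n_mirnas = len(mirna_ids)
    cluster_idx = np.array([names.index(cluster_of[m]) for m in mirna_ids])

    loadings = rng.normal(config.loading_mean, config.loading_sd, n_mirnas)
    ct_base = rng.normal(config.ct_base_mean, config.ct_base_sd, n_mirnas)

    corr = {g: np.asarray(m, dtype=float) for g, m in config.factor_corr.items()}
    chol = {g: np.linalg.cholesky(corr[g] + 1e-12 * np.eye(len(names))) for g in corr}
    scale = {
        g: np.array(
            [config.loading_scale.get(g, {}).get(name, 1.0) for name in names]
        )
        for g in (TERM, PTB)
    }

    def draw_sample(group: str):
        f = chol[group] @ rng.standard_normal(len(names))
        lam = loadings * scale[group][cluster_idx]
        dct = lam * f[cluster_idx] + rng.normal(0.0, config.noise_sd, n_mirnas)
        ct = ct_base - dct
        censored = ct > config.censor_ct
        if config.outcome_on == "score":
            score = np.full(len(names), 0.0)
            for c in range(len(names)):
                obs = (cluster_idx == c) & ~censored
                score[c] = dct[obs].mean() if obs.any() else 0.0
            lin = sum(
                config.outcome_betas.get(names[c], 0.0) * score[c]
                for c in range(len(names))
            )
        else:
            score = None
            lin = sum(
                config.outcome_betas.get(names[c], 0.0) * f[c]
                for c in range(len(names))
            )
        ga = config.ga_intercept + lin + rng.normal(0.0, config.outcome_noise_sd)
        return f, dct, ct, censored, score, ga

    accepted: dict[str, list] = {TERM: [], PTB: []}
    max_draws = 2000 * config.n_pairs
    for _ in range(max_draws):
        if all(len(accepted[g]) >= config.n_pairs for g in (TERM, PTB)):
            break
        group = TERM if len(accepted[TERM]) < config.n_pairs else PTB
        f, dct, ct, censored, score, ga = draw_sample(group)
        label = PTB if ga <= config.ptb_cutoff else TERM
        if label == group:
            accepted[group].append((f, dct, ct, censored, score, ga))
    if any(len(accepted[g]) < config.n_pairs for g in (TERM, PTB)):
        raise ValidationError(
            "rejection sampling failed to reach the target group sizes; "
            "outcome effects and ptb_cutoff are inconsistent"
        )

    sample_ids, groups, pair_ids = [], [], []
    rows = []
    for k in range(config.n_pairs):
        for group in (TERM, PTB):
            rows.append(accepted[group][k])
            sample_ids.append(f"S{len(sample_ids) + 1:02d}")
            groups.append(group)
            pair_ids.append(f"P{k + 1:02d}")

    factors = np.array([r[0] for r in rows])
    dct = np.array([r[1] for r in rows])
    ct = np.array([r[2] for r in rows])
    censored = np.array([r[3] for r in rows])
    ga = np.array([r[5] for r in rows])
    scores_used = (
        np.array([r[4] for r in rows]) if config.outcome_on == "score" else None
    )

    bw = (
        config.bw_intercept
        + config.bw_per_week * (ga - config.ga_intercept)
        + rng.normal(0.0, config.bw_noise_sd, len(ga))
    )
    c19_pos = names.index("c19mc") if "c19mc" in names else None
    hc = (
        config.hc_intercept
        + config.hc_per_week * (ga - config.ga_intercept)
        + (config.hc_c19_beta * factors[:, c19_pos] if c19_pos is not None else 0.0)
        + rng.normal(0.0, config.hc_noise_sd, len(ga))
    )

    n = len(sample_ids)
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": groups,
                "pair_id": pair_ids,
                "gestational_age_birth": ga,
                "birth_weight": np.round(bw, 0),
                "head_circumference": np.round(hc, 1),
                "bmi": np.round(np.clip(rng.normal(25.7, 5.35, n), 16, 45), 1),
                "gravida": 1 + rng.poisson(1.7, n).clip(max=5),
                "history_ptb": rng.random(n) < 10 / 42,
                "fetal_sex": rng.integers(0, 2, n),
            }
        )
    )
    ct_matrix = CtMatrix(
        sample_ids=sample_ids,
        mirna_ids=mirna_ids,
        ct=np.where(censored, np.nan, ct),
        amplified=~censored,
    )
    truth = SimulationTruth(
        factors=pd.DataFrame(factors, index=sample_ids, columns=names),
        loadings=pd.Series(loadings, index=mirna_ids),
        ct_base=pd.Series(ct_base, index=mirna_ids),
        cluster_of=cluster_of,
        group_of=dict(zip(sample_ids, groups)),
        dct=pd.DataFrame(dct, index=sample_ids, columns=mirna_ids),
        censored=pd.DataFrame(censored, index=sample_ids, columns=mirna_ids),
        scores_used=(
            pd.DataFrame(scores_used, index=sample_ids, columns=names)
            if scores_used is not None
            else None
        ),
        outcome_betas=dict(config.outcome_betas),
        outcome_on=config.outcome_on,
        config=config,
    )
    return ct_matrix, annotations, meta, truth


def write_cohort(
    outdir: str | Path, config: SimulationConfig | None = None
) -> SimulationTruth:
    """Simulate and write ct.csv, annotations.gff3, families.tsv,
    locus_labels.tsv, metadata.csv and truth.json into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or paper_default_config()
    ct, annotations, meta, truth = simulate_cohort(config)
    write_ct_matrix(ct, outdir / "ct.csv")
    write_annotations_gff3(annotations, outdir / "annotations.gff3")
    with open(outdir / "families.tsv", "w") as fh:
        for mid, fam in family_table(config).items():
            fh.write(f"{mid}\t{fam}\n")
    with open(outdir / "locus_labels.tsv", "w") as fh:
        fh.write("name\tchromosome\tstart\tend\n")
        for lab in locus_labels(config):
            fh.write(f"{lab.name}\t{lab.chromosome}\t{lab.start}\t{lab.end}\n")
    write_metadata(meta, outdir / "metadata.csv")
    truth.to_json(outdir / "truth.json")
    return truth
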