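"""Synthetic pan-cancer cohorts with planted, known effect sizes.

The generator emulates the statistical structure the analyses assume: sample
blocks per cancer type with a minority metastatic fraction; a latent
per-sample EMT axis ``z`` (standard normal, shifted upward by ``emt_shift``
in metastatic samples) that drives mesenchymal genes up and epithelial genes
down; optional genes correlated with ``z`` at a chosen Pearson ρ; copy-number
gain genes with group-specific gain frequencies; sparse Bernoulli mutations;
and exponential survival under proportional hazards with independent
exponential censoring.

Randomness is split into named substreams (latent axis, expression, CNA,
mutation, survival, group assignment) derived from one seed, so e.g. adding
genes to the expression model does not perturb the survival draws.

It makes no attempt to match real marginal expression distributions, batch
effects, or inter-gene co-expression beyond the single latent EMT axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .datamodel import EmtGeneSets, OmicsCohort
from .io import write_cohort, write_json

DEFAULT_MESENCHYMAL = ("CDH2", "FN1", "SNAI1", "SNAI2", "VIM", "TWIST1", "TWIST2", "ZEB2")
DEFAULT_EPITHELIAL = ("CDH1", "CLDN4", "CLDN7", "MUC1", "TJP3")

# TCGA-style cohort codes used to label the simulated cancer-type blocks.
_CANCER_CODES = ("BRCA", "COADREAD", "KIRC", "LIHC", "LUAD", "OV", "PRAD", "HNSC", "SKCM")

_STREAMS = ("assign", "latent", "expression", "cna", "mutation", "survival")


class SimulationConfigError(ValueError):
    """Raised for inconsistent simulation parameters."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort. All rates are per day."""

    seed: int = 0
    n_cancer_types: int = 5
    samples_per_type: int = 200
    metastatic_fraction: float = 0.15
    normal_fraction: float = 0.0
    blood_fraction: float = 0.0
    n_genes: int = 40
    # latent EMT axis and expression model
    emt_shift: float = 1.5          # added to z in metastatic samples
    emt_loading: float = 1.0        # ±loading·z for mesenchymal/epithelial genes
    noise_sd: float = 1.0
    expression_baseline: float = 8.0  # typical log2 RSEM magnitude
    mesenchymal_genes: tuple[str, ...] = DEFAULT_MESENCHYMAL
    epithelial_genes: tuple[str, ...] = DEFAULT_EPITHELIAL
    emt_assoc_genes: dict[str, float] = field(default_factory=dict)  # gene -> ρ
    # copy number: gene -> (gain freq in primary, gain freq in metastatic)
    cna_gain_genes: dict[str, tuple[float, float]] = field(default_factory=dict)
    cna_loss_genes: dict[str, tuple[float, float]] = field(default_factory=dict)
    cna_full_range: bool = False    # split gains over {1,2} and losses over {-1,-2}
    # mutations
    mutation_rates: dict[str, float] = field(default_factory=dict)
    background_mutation_rate: float = 0.02
    # planted expression-signature cluster (binary latent sample group)
    signature_genes: tuple[str, ...] = ()
    signature_shift: float = 2.0
    signature_fraction: float = 0.4
    # survival: covariate key -> log hazard ratio. Keys: "metastatic",
    # "signature_cluster", "mutation:GENE", "gain:GENE", "loss:GENE".
    survival_effects: dict[str, float] = field(default_factory=dict)
    baseline_hazard: float = 1e-3
    censoring_rate: float = 2.5e-4

    def __post_init__(self) -> None:
        self.mesenchymal_genes = tuple(self.mesenchymal_genes)
        self.epithelial_genes = tuple(self.epithelial_genes)
        self.signature_genes = tuple(self.signature_genes)
        self.cna_gain_genes = {g: tuple(v) for g, v in self.cna_gain_genes.items()}
        self.cna_loss_genes = {g: tuple(v) for g, v in self.cna_loss_genes.items()}
        self.validate()

    def validate(self) -> None:
        fracs = {
            "metastatic_fraction": self.metastatic_fraction,
            "normal_fraction": self.normal_fraction,
            "blood_fraction": self.blood_fraction,
            "signature_fraction": self.signature_fraction,
            "background_mutation_rate": self.background_mutation_rate,
        }
        fracs.update({f"mutation_rates[{g}]": r for g, r in self.mutation_rates.items()})
        for gmap, name in ((self.cna_gain_genes, "cna_gain_genes"),
                           (self.cna_loss_genes, "cna_loss_genes")):
            for g, (pp, pm) in gmap.items():
                fracs[f"{name}[{g}].primary"] = pp
                fracs[f"{name}[{g}].metastatic"] = pm
        for name, p in fracs.items():
            if not 0.0 <= p <= 1.0:
                raise SimulationConfigError(f"{name} = {p} outside [0, 1]")
        if self.metastatic_fraction + self.normal_fraction + self.blood_fraction > 1.0:
            raise SimulationConfigError("sample-type fractions exceed 1")
        for g, rho in self.emt_assoc_genes.items():
            if not -1.0 <= rho <= 1.0:
                raise SimulationConfigError(f"emt_assoc_genes[{g}] = {rho} outside [-1, 1]")
        if self.baseline_hazard <= 0 or self.censoring_rate <= 0:
            raise SimulationConfigError("baseline_hazard and censoring_rate must be > 0")
        if self.noise_sd < 0:
            raise SimulationConfigError("noise_sd must be non-negative")
        if len(self.gene_universe()) > self.n_genes:
            raise SimulationConfigError(
                f"{len(self.gene_universe())} named genes exceed n_genes={self.n_genes}"
            )
        for key in self.survival_effects:
            kind = key.split(":", 1)[0]
            if key not in ("metastatic", "signature_cluster") and kind not in (
                "mutation", "gain", "loss"
            ):
                raise SimulationConfigError(f"unknown survival covariate {key!r}")

    def gene_universe(self, padded: bool = False) -> tuple[str, ...]:
        """Ordered gene list: named genes first, then NULLxxx filler to n_genes."""
        out: dict[str, None] = {}
        for g in (
            *self.mesenchymal_genes,
            *self.epithelial_genes,
            *self.emt_assoc_genes,
            *self.cna_gain_genes,
            *self.cna_loss_genes,
            *self.mutation_rates,
            *self.signature_genes,
        ):
            out[str(g).upper()] = None
        for key in self.survival_effects:
            if ":" in key:
                out[key.split(":", 1)[1].upper()] = None
        if padded:
            i = 0
            while len(out) < self.n_genes:
                i += 1
                name = f"NULL{i:03d}"
                if name not in out:
                    out[name] = None
        return tuple(out)

    # -- (de)serialization for CLI configs --------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        d["cna_gain_genes"] = {g: list(v) for g, v in self.cna_gain_genes.items()}
        d["cna_loss_genes"] = {g: list(v) for g, v in self.cna_loss_genes.items()}
        return d


def default_config(seed: int = 0) -> SimulationConfig:
    """Showcase configuration mirroring the planted-effect study conditions.

    Seven cancer-type blocks of 200 samples with 15% metastatic; a metastatic
    EMT shift of 1.5 latent-axis SD; the five signature genes correlated with
    the EMT axis at ρ = 0.7; six genes with copy-number gain frequency 0.10
    (primary) vs 0.45 (metastatic); frequent TP53 and occasional STK11
    mutations over a 2% background; and hazard increased by e^0.5 for TP53
    mutants and e^0.7 for the high-signature-expression group.
    """
    sig = ("CPT1C", "CAV1", "CD36", "MLXIPL", "CYP2E1")
    return SimulationConfig(
        seed=seed,
        n_cancer_types=7,
        samples_per_type=200,
        metastatic_fraction=0.15,
        n_genes=70,
        emt_assoc_genes={g: 0.7 for g in sig},
        cna_gain_genes={
            g: (0.10, 0.45) for g in ("SCO2", "MLXIPL", "PPARA", "PPARD", "CAV1", "CD36")
        },
        mutation_rates={"TP53": 0.30, "STK11": 0.08},
        signature_genes=sig,
        survival_effects={"mutation:TP53": 0.5, "signature_cluster": 0.7},
    )


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def generate_cohort(config: SimulationConfig) -> OmicsCohort:
    """Generate one cohort; deterministic given ``config`` (incl. its seed)."""
    rng = _rngs(config.seed)
    genes = config.gene_universe(padded=True)
    n_per = config.samples_per_type
    types = [_CANCER_CODES[i] if i < len(_CANCER_CODES) else f"CT{i + 1:02d}"
             for i in range(config.n_cancer_types)]

    sample_ids: list[str] = []
    cancer_type: list[str] = []
    sample_type: list[str] = []
    for ct in types:
        n_met = int(round(config.metastatic_fraction * n_per))
        n_norm = int(round(config.normal_fraction * n_per))
        n_blood = int(round(config.blood_fraction * n_per))
        n_prim = n_per - n_met - n_norm - n_blood
        block = (["primary"] * n_prim + ["metastatic"] * n_met
                 + ["normal"] * n_norm + ["blood"] * n_blood)
        sample_type.extend(block)
        cancer_type.extend([ct] * n_per)
        sample_ids.extend(f"{ct}-{i:04d}" for i in range(1, n_per + 1))
    n = len(sample_ids)
    is_met = np.array([t == "metastatic" for t in sample_type])

    # planted binary signature cluster (independent of metastatic status)
    in_cluster = rng["assign"].random(n) < config.signature_fraction

    # latent EMT axis
    z = rng["latent"].standard_normal(n) + config.emt_shift * is_met

    mes = set(config.mesenchymal_genes)
    epi = set(config.epithelial_genes)
    sig = set(config.signature_genes)
    rows = np.empty((len(genes), n))
    for i, g in enumerate(genes):
        eps = rng["expression"].standard_normal(n)
        if g in mes:
            row = config.emt_loading * z + config.noise_sd * eps
        elif g in epi:
            row = -config.emt_loading * z + config.noise_sd * eps
        elif g in config.emt_assoc_genes:
            rho = config.emt_assoc_genes[g]
            # unit-variance noise so corr(expr, z) = rho exactly in expectation
            row = rho * z + np.sqrt(1.0 - rho * rho) * eps
        else:
            row = config.noise_sd * eps
        if g in sig:
            row = row + config.signature_shift * in_cluster
        rows[i] = config.expression_baseline + row
    expression = pd.DataFrame(np.round(rows, 4), index=list(genes), columns=sample_ids)
    expression.index.name = "gene"

    cna = np.zeros((len(genes), n), dtype=int)
    for i, g in enumerate(genes):
        if g in config.cna_gain_genes:
            pp, pm = config.cna_gain_genes[g]
            p = np.where(is_met, pm, pp)
            gain = rng["cna"].random(n) < p
            if config.cna_full_range:
                high = rng["cna"].random(n) < 0.5
                cna[i] = np.where(gain, np.where(high, 2, 1), 0)
            else:
                cna[i] = gain.astype(int)
        if g in config.cna_loss_genes:
            pp, pm = config.cna_loss_genes[g]
            p = np.where(is_met, pm, pp)
            loss = rng["cna"].random(n) < p
            if config.cna_full_range:
                deep = rng["cna"].random(n) < 0.5
                lvals = np.where(loss, np.where(deep, -2, -1), 0)
            else:
                lvals = -loss.astype(int)
            cna[i] = np.where(cna[i] != 0, cna[i], lvals)
    cna_df = pd.DataFrame(cna, index=list(genes), columns=sample_ids)
    cna_df.index.name = "gene"

    mut = np.zeros((len(genes), n), dtype=int)
    for i, g in enumerate(genes):
        rate = config.mutation_rates.get(g, config.background_mutation_rate)
        mut[i] = (rng["mutation"].random(n) < rate).astype(int)
    mut_df = pd.DataFrame(mut, index=list(genes), columns=sample_ids)
    mut_df.index.name = "gene"

    # proportional-hazards exponential survival with exponential censoring
    log_hr = np.zeros(n)
    for key, beta in config.survival_effects.items():
        if key == "metastatic":
            x = is_met.astype(float)
        elif key == "signature_cluster":
            x = in_cluster.astype(float)
        else:
            kind, gene = key.split(":", 1)
            gene = gene.upper()
            if kind == "mutation":
                x = mut_df.loc[gene].to_numpy(dtype=float)
            elif kind == "gain":
                x = (cna_df.loc[gene].to_numpy() >= 1).astype(float)
            else:  # loss
                x = (cna_df.loc[gene].to_numpy() <= -1).astype(float)
        log_hr = log_hr + beta * x
    hazard = config.baseline_hazard * np.exp(log_hr)
    t_event = rng["survival"].exponential(1.0 / hazard)
    t_cens = rng["survival"].exponential(1.0 / config.censoring_rate, size=n)
    os_days = np.round(np.minimum(t_event, t_cens), 2)
    os_event = (t_event <= t_cens).astype(int)

    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cancer_type": cancer_type,
            "sample_type": sample_type,
            "os_days": os_days,
            "os_event": os_event,
        }
    )
    return OmicsCohort(expression=expression, mutation=mut_df, cna=cna_df, clinical=clinical)


def planted_truth(config: SimulationConfig) -> dict:
    """Machine-readable ledger of the effects planted by ``generate_cohort``.

    Empty effect maps are omitted, so a fully null configuration yields ``{}``.
    """
    truth: dict = {}
    if config.emt_assoc_genes:
        truth["emt_assoc_genes"] = dict(config.emt_assoc_genes)
    if config.cna_gain_genes:
        truth["cna_gain_genes"] = {g: list(v) for g, v in config.cna_gain_genes.items()}
    if config.cna_loss_genes:
        truth["cna_loss_genes"] = {g: list(v) for g, v in config.cna_loss_genes.items()}
    if config.mutation_rates:
        truth["mutation_rates"] = dict(config.mutation_rates)
    if config.survival_effects:
        truth["survival_effects"] = dict(config.survival_effects)
    if config.signature_genes:
        truth["signature_genes"] = list(config.signature_genes)
        truth["signature_shift"] = config.signature_shift
    if config.emt_shift:
        truth["emt_shift"] = config.emt_shift
    return truth


def emt_sets_for(config: SimulationConfig) -> EmtGeneSets:
    """EMT gene sets matching the simulated mesenchymal/epithelial genes."""
    return EmtGeneSets.from_lists(config.mesenchymal_genes, config.epithelial_genes)


def simulate_to_dir(config: SimulationConfig, out_dir: str | Path) -> OmicsCohort:
    """Generate a cohort, write its four TSVs plus ``truth.json``."""
    cohort = generate_cohort(config)
    out = Path(out_dir)
    write_cohort(cohort, out)
    write_json(planted_truth(config), out / "truth.json")
    return cohort
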