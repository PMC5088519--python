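"""Synthetic expression data with the structure the analysis assumes.

The generator emulates a sleep-deprivation / recovery-sleep microarray
study: per-gene log2 expression is

    y[g, s] = baseline_g
              + A_g * cos(2*pi*(zt_s - phi_g) / 24)        (circadian genes)
              + beta_g(group_s)                            (treatment)
              + (W @ alpha)[s, g]                          (unwanted factors)
              + eps[g, s]

Treatment effects appear at the end of sleep deprivation (logFC_0) and
decay exponentially during recovery sleep toward a zero asymptote,

    logFC_t = LA + (logFC_0 - LA) * exp(-t / tau_d),   LA = 0,

with t the hours of recovery sleep (SD -> 0, RS1 -> 1, ... RS6 -> 6) and a
per-gene time constant tau_d that is either fast or slow.  A small "late"
class is unaffected by deprivation but induced by the sixth recovery hour.
Unwanted variation is a low-rank factor term W @ alpha shared across
replicates and independent of treatment, which is exactly the structure
replicate-based factor normalization can learn and remove.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import ControlGeneSets, ExpressionDataset

__all__ = [
    "GroupSpec",
    "SimulationConfig",
    "SimulationTruth",
    "MetaStudySpec",
    "RECOVERY_HOURS",
    "default_design",
    "generate",
    "generate_meta",
]

#: Hours of recovery sleep at sacrifice for each treated group.
RECOVERY_HOURS = {"SD": 0.0, "RS1": 1.0, "RS2": 2.0, "RS3": 3.0, "RS6": 6.0}

#: Sacrifice circadian time (ZT) per group: deprivation runs ZT0-ZT6,
#: recovery-sleep groups are sacrificed 1/2/3/6 h later, undisturbed
#: controls at the ZT printed in their label.
GROUP_ZT = {
    "CC0": 0.0,
    "CC6": 6.0,
    "CC7": 7.0,
    "CC8": 8.0,
    "CC11": 11.0,
    "SD": 6.0,
    "RS1": 7.0,
    "RS2": 8.0,
    "RS3": 9.0,
    "RS6": 12.0,
}


@dataclass(frozen=True)
class GroupSpec:
    group: str
    zt_time: float
    n_replicates: int


def default_design() -> list:
    """The 96-array, 10-group design of the emulated study.

    Ten groups (five undisturbed controls, sleep deprivation, four
    recovery-sleep durations) totalling 96 arrays: six groups of 10 and
    four of 9.
    """
    sizes = {
        "CC0": 10, "CC6": 10, "CC7": 10, "CC8": 10, "CC11": 9,
        "SD": 10, "RS1": 9, "RS2": 9, "RS3": 10, "RS6": 9,
    }
    return [GroupSpec(g, GROUP_ZT[g], n) for g, n in sizes.items()]


@dataclass
class SimulationConfig:
    """Generative settings; defaults are the emulated study conditions.

    Effect sizes are absolute log2 fold changes at the end of sleep
    deprivation, drawn uniformly from ``effect_range``. Per-gene residual
    standard deviations follow a scaled inverse-chi-square law with scale
    ``sigma_noise`` and ``noise_prior_df`` degrees of freedom — the prior
    the moderated-t analysis assumes. ``batch_strength`` scales the
    loadings of the ``k_true`` latent unwanted factors.
    """

    n_genes: int = 10000
    design: list = field(default_factory=default_design)
    k_true: int = 3
    sigma_noise: float = 0.2
    noise_prior_df: float = 5.0
    frac_up: float = 0.05
    frac_down: float = 0.05
    frac_late: float = 0.005
    effect_range: tuple = (0.5, 2.0)
    tau_fast: float = 1.3
    tau_slow: float = 4.5
    #: overall fast fraction; when None the per-direction fractions apply
    frac_fast: float = None
    #: most downregulated transcripts recover fast, most upregulated slowly
    frac_fast_down: float = 0.95
    frac_fast_up: float = 0.12
    frac_circadian: float = 0.10
    circadian_amplitude_range: tuple = (0.5, 1.5)
    n_negative_controls: int = 1000
    n_positive_controls: int = 50
    batch_strength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_up", "frac_down", "frac_late", "frac_fast",
            "frac_fast_down", "frac_fast_up", "frac_circadian",
        ):
            v = getattr(self, name)
            if v is None and name == "frac_fast":
                continue
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_up + self.frac_down + self.frac_late > 1.0:
            raise ValueError("frac_up + frac_down + frac_late exceeds 1")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        for name in ("n_negative_controls", "n_positive_controls"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.k_true < 0:
            raise ValueError("k_true must be >= 0")
        if not self.tau_fast < self.tau_slow:
            raise ValueError("tau_fast must be smaller than tau_slow")
        if not self.effect_range[0] <= self.effect_range[1]:
            raise ValueError("effect_range must be (low, high)")
        self.design = [g if isinstance(g, GroupSpec) else GroupSpec(*g) for g in self.design]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["design"] = [(g.group, g.zt_time, g.n_replicates) for g in self.design]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "design" in d:
            d["design"] = [GroupSpec(*g) for g in d["design"]]
        if "effect_range" in d:
            d["effect_range"] = tuple(d["effect_range"])
        if "circadian_amplitude_range" in d:
            d["circadian_amplitude_range"] = tuple(d["circadian_amplitude_range"])
        return cls(**d)


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset.

    ``genes`` has one row per gene: class (fast/slow/late/circadian/null),
    sign, logfc0, tau, circadian flag/amplitude/phase and residual sd.
    ``beta`` holds the true per-group treatment effect per gene; ``W`` and
    ``alpha`` the latent unwanted factors and their loadings.
    """

    genes: pd.DataFrame
    beta: pd.DataFrame
    W: pd.DataFrame
    alpha: pd.DataFrame

    def write(self, path) -> None:
        out = self.genes.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.6g")


def _make_design_table(design, study: str, platform: str) -> pd.DataFrame:
    rows = []
    for spec in design:
        for i in range(spec.n_replicates):
            rows.append(
                {
                    "sample_id": f"{study}.{spec.group}.r{i + 1}",
                    "group": spec.group,
                    "zt_time": spec.zt_time,
                    "replicate_group": f"{study}.{spec.group}",
                    "study": study,
                    "platform": platform,
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def _treatment_effect(group: str, lfc0: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """True logFC of affected genes in ``group`` (zero asymptote decay)."""
    if group not in RECOVERY_HOURS:
        return np.zeros_like(lfc0)
    t = RECOVERY_HOURS[group]
    return lfc0 * np.exp(-t / tau)


def _simulate_genes(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_genes
    genes = pd.DataFrame(
        {
            "cls": np.array(["null"] * n, dtype=object),
            "sign": np.zeros(n),
            "logfc0": np.zeros(n),
            "tau": np.full(n, np.nan),
            "is_circadian": np.zeros(n, bool),
            "circ_amp": np.zeros(n),
            "circ_phase": np.zeros(n),
        },
        index=pd.Index([f"G{i:06d}" for i in range(n)], name="gene_id"),
    )
    n_up = round(config.frac_up * n)
    n_down = round(config.frac_down * n)
    n_late = round(config.frac_late * n)
    perm = rng.permutation(n)
    up_idx = perm[:n_up]
    down_idx = perm[n_up : n_up + n_down]
    late_idx = perm[n_up + n_down : n_up + n_down + n_late]

    affected = np.concatenate([up_idx, down_idx])
    lo, hi = config.effect_range
    mag = rng.uniform(lo, hi, size=affected.size)
    sign = np.concatenate([np.ones(n_up), -np.ones(n_down)])
    fast_mask = np.zeros(affected.size, bool)
    if config.frac_fast is not None:
        n_fast = round(config.frac_fast * affected.size)
        fast_mask[rng.choice(affected.size, size=n_fast, replace=False)] = True
    else:
        n_fast_up = round(config.frac_fast_up * n_up)
        n_fast_down = round(config.frac_fast_down * n_down)
        if n_fast_up:
            fast_mask[rng.choice(n_up, size=n_fast_up, replace=False)] = True
        if n_fast_down:
            fast_mask[n_up + rng.choice(n_down, size=n_fast_down, replace=False)] = True

    genes.iloc[affected, genes.columns.get_loc("sign")] = sign
    genes.iloc[affected, genes.columns.get_loc("logfc0")] = sign * mag
    genes.iloc[affected, genes.columns.get_loc("tau")] = np.where(
        fast_mask, config.tau_fast, config.tau_slow
    )
    genes.iloc[affected, genes.columns.get_loc("cls")] = np.where(fast_mask, "fast", "slow")

    genes.iloc[late_idx, genes.columns.get_loc("cls")] = "late"
    genes.iloc[late_idx, genes.columns.get_loc("sign")] = 1.0
    genes.iloc[late_idx, genes.columns.get_loc("logfc0")] = 0.0

    n_circ = round(config.frac_circadian * n)
    circ_idx = rng.choice(n, size=n_circ, replace=False)
    a_lo, a_hi = config.circadian_amplitude_range
    genes.iloc[circ_idx, genes.columns.get_loc("is_circadian")] = True
    genes.iloc[circ_idx, genes.columns.get_loc("circ_amp")] = rng.uniform(a_lo, a_hi, n_circ)
    genes.iloc[circ_idx, genes.columns.get_loc("circ_phase")] = rng.uniform(0, 24, n_circ)
    is_null = (genes["cls"] == "null").to_numpy()
    genes.loc[is_null & genes["is_circadian"].to_numpy(), "cls"] = "circadian"
    return genes


def _true_beta(config: SimulationConfig, genes: pd.DataFrame) -> pd.DataFrame:
    """Per-group true treatment effect (genes x groups)."""
    group_names = [g.group for g in config.design]
    lfc0 = genes["logfc0"].to_numpy()
    tau = genes["tau"].to_numpy()
    beta = pd.DataFrame(0.0, index=genes.index, columns=group_names)
    safe_tau = np.where(np.isfinite(tau), tau, 1.0)
    affected = genes["cls"].isin(["fast", "slow"]).to_numpy()
    for g in group_names:
        eff = _treatment_effect(g, lfc0, safe_tau)
        beta[g] = np.where(affected, eff, 0.0)
    return beta


def generate(config: SimulationConfig):
    """Simulate one study.

    Returns ``(ExpressionDataset, SimulationTruth, ControlGeneSets)``.
    Negative controls are sampled from null, non-circadian genes; positive
    controls from affected genes whose |logFC_0| exceeds the 60th
    percentile of the effect-size distribution. Fully reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    genes = _simulate_genes(config, rng)
    design = _make_design_table(config.design, study="sim", platform="simarray")
    n, S = config.n_genes, len(design)

    beta = _true_beta(config, genes)
    late = (genes["cls"] == "late").to_numpy()
    if late.any() and "RS6" in beta.columns:
        lo, hi = config.effect_range
        beta.loc[late, "RS6"] = rng.uniform(lo, hi, late.sum())

    baseline = rng.uniform(5.0, 10.0, size=n)
    sigma2 = config.sigma_noise**2 * config.noise_prior_df / rng.chisquare(
        config.noise_prior_df, size=n
    )
    sigma = np.sqrt(sigma2)

    if config.k_true > 0:
        W = rng.standard_normal((S, config.k_true))
        gene_factor = rng.choice([0.5, 1.0, 3.0], size=n, p=[0.6, 0.3, 0.1])
        alpha = rng.standard_normal((config.k_true, n)) * config.batch_strength * gene_factor
    else:
        W = np.zeros((S, 0))
        alpha = np.zeros((0, n))

    zt = design["zt_time"].to_numpy()
    amp = genes["circ_amp"].to_numpy()
    phase = genes["circ_phase"].to_numpy()
    circ = amp[:, None] * np.cos(2 * np.pi * (zt[None, :] - phase[:, None]) / 24.0)

    group_effect = beta[design["group"]].to_numpy()  # genes x samples
    eps = rng.standard_normal((n, S)) * sigma[:, None]
    values = baseline[:, None] + circ + group_effect + (W @ alpha).T + eps

    matrix = pd.DataFrame(values, index=genes.index, columns=design.index)
    dataset = ExpressionDataset(matrix=matrix, design=design)

    truth = SimulationTruth(
        genes=genes.assign(sigma=sigma, baseline=baseline),
        beta=beta,
        W=pd.DataFrame(W, index=design.index, columns=[f"W{j+1}" for j in range(W.shape[1])]),
        alpha=pd.DataFrame(
            alpha, index=[f"W{j+1}" for j in range(alpha.shape[0])], columns=genes.index
        ),
    )
    controls = _draw_controls(config, genes, rng)
    return dataset, truth, controls


def _draw_controls(
    config: SimulationConfig, genes: pd.DataFrame, rng: np.random.Generator
) -> ControlGeneSets:
    negative: set = set()
    if config.n_negative_controls:
        eligible_neg = genes.index[(genes["cls"] == "null") & ~genes["is_circadian"]]
        if len(eligible_neg) < config.n_negative_controls:
            raise ValueError(
                f"requested {config.n_negative_controls} negative controls but only "
                f"{len(eligible_neg)} null non-circadian genes are available"
            )
        negative = set(rng.choice(eligible_neg, size=config.n_negative_controls, replace=False))

    positive: dict = {}
    if config.n_positive_controls:
        lo, hi = config.effect_range
        q60 = lo + 0.6 * (hi - lo)
        strong = genes.index[
            genes["cls"].isin(["fast", "slow"]) & (genes["logfc0"].abs() > q60)
        ]
        if len(strong) < config.n_positive_controls:
            raise ValueError(
                f"requested {config.n_positive_controls} positive controls but only "
                f"{len(strong)} affected genes exceed the 60th-percentile effect size"
            )
        chosen = set(rng.choice(strong, size=config.n_positive_controls, replace=False))
        from .de import PAPER_CONTRASTS  # late import to avoid a cycle

        positive = {c.name: set(chosen) for c in PAPER_CONTRASTS}
    return ControlGeneSets(negative=negative, positive=positive)


# ---------------------------------------------------------------------------
# Multi-study (meta-analysis) generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetaStudySpec:
    """One study of a simulated meta-analysis.

    ``platform_offset_sd`` / ``lab_offset_sd`` scale per-gene additive
    offsets shared by all samples of the same platform / study; platform
    offsets are shared between studies run on the same platform. Each
    study observes a random fraction ``gene_frac`` of the shared gene
    namespace through its own probeset ids.
    """

    name: str
    platform: str
    design: tuple = (("SD", 6.0, 5), ("CC6", 6.0, 5))
    platform_offset_sd: float = 2.0
    lab_offset_sd: float = 1.0
    gene_frac: float = 0.9
    n_multi_gene_probesets: int = 5
    n_duplicate_probesets: int = 5


def generate_meta(config: SimulationConfig, studies):
    """Simulate >= 2 studies sharing true treatment effects.

    Returns ``(datasets, mapping, truth, expected_genes)`` where
    ``datasets`` carry per-study probeset ids, ``mapping`` is the
    probeset -> gene table covering all studies (including planted
    multi-mapping rows), and ``expected_genes`` is the set of shared gene
    ids that survive both-direction multi-mapping exclusion and the
    cross-study intersection.
    """
    if len(studies) < 2:
        raise ValueError("a meta-analysis simulation needs at least 2 studies")
    rng = np.random.default_rng(config.seed)
    genes = _simulate_genes(config, rng)
    beta = _true_beta(config, genes)
    baseline = rng.uniform(5.0, 10.0, size=config.n_genes)
    gene_ids = genes.index.to_numpy()

    platform_offsets: dict = {}
    datasets, mapping_rows = [], []
    per_study_clean: list = []
    per_study_genes: list = []
    for spec in studies:
        spec_design = [g if isinstance(g, GroupSpec) else GroupSpec(*g) for g in spec.design]
        design = _make_design_table(spec_design, study=spec.name, platform=spec.platform)
        S = len(design)
        keep = np.sort(
            rng.choice(config.n_genes, size=round(spec.gene_frac * config.n_genes), replace=False)
        )
        sub_genes = gene_ids[keep]
        per_study_genes.append(set(sub_genes))
        if spec.platform not in platform_offsets:
            platform_offsets[spec.platform] = (
                rng.standard_normal(config.n_genes) * spec.platform_offset_sd
            )
        p_off = platform_offsets[spec.platform][keep]
        l_off = rng.standard_normal(len(keep)) * spec.lab_offset_sd

        sigma = config.sigma_noise * np.sqrt(
            config.noise_prior_df / rng.chisquare(config.noise_prior_df, size=len(keep))
        )
        if config.k_true > 0:
            W = rng.standard_normal((S, config.k_true))
            alpha = rng.standard_normal((config.k_true, len(keep))) * config.batch_strength
        else:
            W, alpha = np.zeros((S, 0)), np.zeros((0, len(keep)))
        group_effect = beta.iloc[keep][design["group"]].to_numpy()
        eps = rng.standard_normal((len(keep), S)) * sigma[:, None]
        values = (
            baseline[keep][:, None]
            + group_effect
            + p_off[:, None]
            + l_off[:, None]
            + (W @ alpha).T
            + eps
        )

        probesets = np.array([f"{spec.name}_ps{i:06d}" for i in keep])
        matrix = pd.DataFrame(values, index=probesets, columns=design.index)
        # planted multi-mapping: probesets hitting 2 genes, genes hit twice
        clean = set(sub_genes)
        multi_ps = rng.choice(len(keep), size=min(spec.n_multi_gene_probesets, len(keep)), replace=False)
        absent = np.setdiff1d(np.arange(config.n_genes), keep)
        for i, j in enumerate(multi_ps):
            # second mapped gene drawn from outside this study so only the
            # ambiguous probeset's own gene loses its measurement here
            if absent.size:
                other = gene_ids[absent[i % absent.size]]
            else:
                other = gene_ids[(keep[j] + 1) % config.n_genes]
            mapping_rows.append((probesets[j], other))
            clean.discard(sub_genes[j])
        dup_candidates = [j for j in range(len(keep)) if j not in set(multi_ps)]
        dup_ps = rng.choice(
            dup_candidates, size=min(spec.n_duplicate_probesets, len(dup_candidates)), replace=False
        )
        extra_rows = {}
        for j in dup_ps:
            extra_id = f"{spec.name}_dup{j:06d}"
            mapping_rows.append((extra_id, sub_genes[j]))
            extra_rows[extra_id] = values[j] + rng.standard_normal(S) * sigma[j]
            clean.discard(sub_genes[j])
        if extra_rows:
            matrix = pd.concat(
                [matrix, pd.DataFrame(extra_rows, index=design.index).T]
            )
        mapping_rows.extend(zip(probesets, sub_genes))
        per_study_clean.append(clean)
        datasets.append(ExpressionDataset(matrix=matrix, design=design))

    overlap = set.intersection(*per_study_genes)
    if not overlap:
        raise ValueError("simulated studies share no genes")
    expected = set.intersection(*per_study_clean)
    mapping = pd.DataFrame(mapping_rows, columns=["probeset_id", "gene_id"])
    truth = SimulationTruth(
        genes=genes,
        beta=beta,
        W=pd.DataFrame(index=pd.Index([], name="sample_id")),
        alpha=pd.DataFrame(),
    )
    return datasets, mapping, truth, expected
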