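"""Negative-binomial count simulator for the split-root resupply design.

Generates genes x samples count matrices for the nine-group design
(four shoot groups: control CK_Sh, deficient S0_Sh, homogeneous resupply
SR_Sh, heterogeneous resupply SP_Sh; five root groups: CK_R, S0_R,
whole-root resupply SR_R, and the two split halves SPSR_R / SPS0_R) with
known, labelled response classes planted into the means, so that every
downstream stage — normalisation, differential testing, recovery
classification — can be checked against ground truth.

Counts follow NB(mean mu, variance mu + phi*mu^2); phi = 0 degenerates to
Poisson. A planted gene's group means are its baseline mean times a
multiplicative pattern factor (2**delta during deficiency, 1 after
recovery), times a per-sample library-size factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SHOOT_GROUPS = ("CK_Sh", "S0_Sh", "SR_Sh", "SP_Sh")
ROOT_GROUPS = ("CK_R", "S0_R", "SR_R", "SPSR_R", "SPS0_R")
DEFAULT_GROUPS = SHOOT_GROUPS + ROOT_GROUPS

RESPONSE_CLASSES = ("local", "systemic", "both", "none", "unrecovered")
PLANTED_CLASSES = tuple(f"{d}_{c}" for d in ("up", "down") for c in RESPONSE_CLASSES)
ALL_CLASSES = ("background",) + PLANTED_CLASSES

#: default planted-class mix: ~12% of genes respond to deficiency, most of
#: them recovering in both split halves or not at all, systemic genes rare —
#: the qualitative ordering seen in split-root studies.
DEFAULT_CLASS_PROPORTIONS = {
    "background": 0.88,
    "up_local": 0.01,
    "up_systemic": 0.005,
    "up_both": 0.01,
    "up_none": 0.015,
    "up_unrecovered": 0.02,
    "down_local": 0.01,
    "down_systemic": 0.005,
    "down_both": 0.01,
    "down_none": 0.015,
    "down_unrecovered": 0.02,
}


def _group_tissue(group: str) -> str:
    return "shoot" if group.endswith("_Sh") else "root"


@dataclass
class SimulationDesign:
    """Parameters of one synthetic split-root experiment.

    Attributes
    ----------
    n_genes : number of simulated genes (default matches the ~37,000
        transcripts detected in a rice root/shoot RNA-seq experiment).
    replicates : biological replicates per sample group (>= 2).
    groups : ordered sample-group labels.
    class_proportions : fraction of genes per planted class; must sum to 1.
    effect_log2fc : planted |log2 fold change| delta of the deficiency
        response (deficient mean = baseline * 2**delta for an up gene).
    dispersion : NB dispersion phi; variance = mu + phi*mu^2.
    base_mean_log_range : (lo, hi) bounds of log10 baseline mean; baselines
        are drawn log-uniformly.
    libsize_cv : coefficient of variation of per-sample library-size
        factors (log-normal, renormalised to geometric mean 1).
    gene_length_range : (lo, hi) transcript length bounds in bp.
    shoot_fraction : fraction of genes assigned to the shoot tissue; the
        rest respond (if planted) in the root groups.
    seed : seed for all randomness in planning and count generation.
    """

    n_genes: int = 37_344
    replicates: int = 3
    groups: tuple[str, ...] = DEFAULT_GROUPS
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    effect_log2fc: float = 3.0
    dispersion: float = 0.1
    base_mean_log_range: tuple[float, float] = (0.5, 3.5)
    libsize_cv: float = 0.1
    gene_length_range: tuple[int, int] = (200, 5000)
    shoot_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        if self.effect_log2fc <= 0:
            raise ValueError("effect_log2fc must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.libsize_cv < 0:
            raise ValueError("libsize_cv must be >= 0")
        if not (0.0 <= self.shoot_fraction <= 1.0):
            raise ValueError("shoot_fraction must be in [0, 1]")
        lo, hi = self.gene_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("gene_length_range must be positive and ordered")
        unknown = set(self.class_proportions) - set(ALL_CLASSES)
        if unknown:
            raise ValueError(f"unknown planted classes: {sorted(unknown)}")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_proportions sum to {total!r}, expected 1")
        if any(v < 0 for v in self.class_proportions.values()):
            raise ValueError("class proportions must be non-negative")

    @property
    def sample_names(self) -> list[str]:
        return [f"{g}_{r}" for g in self.groups for r in range(1, self.replicates + 1)]

    def sample_sheet(self) -> pd.DataFrame:
        """Sample metadata: sample, group, tissue, condition, replicate."""
        rows = []
        for g in self.groups:
            cond = g.rsplit("_", 1)[0]
            for r in range(1, self.replicates + 1):
                rows.append(
                    {
                        "sample": f"{g}_{r}",
                        "group": g,
                        "tissue": _group_tissue(g),
                        "condition": cond,
                        "replicate": r,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class CountMatrix:
    """Integer fragment counts (genes x samples) plus sample metadata."""

    counts: pd.DataFrame  # genes x samples, integer
    samples: pd.DataFrame  # columns: sample, group, tissue, condition, replicate
    gene_lengths: pd.Series  # bp, indexed like counts

    def __post_init__(self) -> None:
        if not (self.counts.values >= 0).all():
            raise ValueError("counts must be non-negative")
        if set(self.samples["sample"]) != set(self.counts.columns):
            raise ValueError("sample sheet does not match count columns")
        if not (self.gene_lengths > 0).all():
            raise ValueError("gene lengths must be positive")

    def group_of(self) -> pd.Series:
        """Map sample name -> group label."""
        return self.samples.set_index("sample")["group"]

    def samples_in(self, group: str) -> list[str]:
        s = self.samples
        out = list(s.loc[s["group"] == group, "sample"])
        if not out:
            raise KeyError(f"no samples in group {group!r}")
        return out


def split_class(response_class: str) -> tuple[str, str]:
    """'up_local' -> ('up', 'local'); 'background' -> ('none', 'background')."""
    if response_class == "background":
        return "none", "background"
    direction, _, cls = response_class.partition("_")
    if direction not in ("up", "down") or cls not in RESPONSE_CLASSES:
        raise ValueError(f"unknown planted class {response_class!r}")
    return direction, cls


def expected_mean_pattern(
    direction: str, response_class: str, effect_log2fc: float
) -> dict[str, float]:
    """Multiplicative factors on the baseline mean for the five root groups.

    For an up-regulated gene with effect delta, the deficient group S0_R sits
    at 2**delta; a group factor of 1 means expression recovered to the
    control level. Recovery happens in the resupplied half only (local),
    the still-deprived half only (systemic), both halves, or neither (none);
    'unrecovered' genes never come back down even under whole-root resupply.
    Down-regulated genes mirror with 2**(-delta).
    """
    if direction == "none":
        if response_class != "background":
            raise ValueError("direction 'none' is reserved for background genes")
        return {g: 1.0 for g in ROOT_GROUPS}
    if direction not in ("up", "down"):
        raise ValueError(f"unknown direction {direction!r}")
    if response_class not in RESPONSE_CLASSES:
        raise ValueError(f"unknown response class {response_class!r}")
    deficient = 2.0 ** (effect_log2fc if direction == "up" else -effect_log2fc)
    pattern = {"CK_R": 1.0, "S0_R": deficient, "SR_R": 1.0}
    if response_class == "local":
        pattern["SPSR_R"], pattern["SPS0_R"] = 1.0, deficient
    elif response_class == "systemic":
        pattern["SPSR_R"], pattern["SPS0_R"] = deficient, 1.0
    elif response_class == "both":
        pattern["SPSR_R"] = pattern["SPS0_R"] = 1.0
    elif response_class == "none":
        pattern["SPSR_R"] = pattern["SPS0_R"] = deficient
    else:  # unrecovered: resupply changes nothing anywhere
        pattern["SR_R"] = pattern["SPSR_R"] = pattern["SPS0_R"] = deficient
    return pattern


def expected_shoot_mean_pattern(
    direction: str, response_class: str, effect_log2fc: float
) -> dict[str, float]:
    """Multiplicative factors for the four shoot groups.

    SR_Sh (homogeneous resupply) recovers every class except 'unrecovered'.
    SP_Sh is the shoot of a heterogeneously resupplied plant: recovery there
    requires the shoot-relayed signal, so only 'systemic' and 'both' genes
    recover; 'local' and 'none' genes stay at the deficient level
    (homogeneous-only responders).
    """
    if direction == "none":
        if response_class != "background":
            raise ValueError("direction 'none' is reserved for background genes")
        return {g: 1.0 for g in SHOOT_GROUPS}
    if direction not in ("up", "down"):
        raise ValueError(f"unknown direction {direction!r}")
    if response_class not in RESPONSE_CLASSES:
        raise ValueError(f"unknown response class {response_class!r}")
    deficient = 2.0 ** (effect_log2fc if direction == "up" else -effect_log2fc)
    pattern = {"CK_Sh": 1.0, "S0_Sh": deficient}
    if response_class == "unrecovered":
        pattern["SR_Sh"] = pattern["SP_Sh"] = deficient
    else:
        pattern["SR_Sh"] = 1.0
        pattern["SP_Sh"] = 1.0 if response_class in ("systemic", "both") else deficient
    return pattern


def expected_shoot_label(response_class: str) -> str:
    """Planted class -> label classify_shoot should assign to a shoot gene."""
    if response_class in ("systemic", "both"):
        return "hetero_responsive"
    if response_class in ("local", "none"):
        return "homo_only"
    if response_class == "unrecovered":
        return "unrecovered"
    raise ValueError(f"unknown response class {response_class!r}")


def plan_truth(design: SimulationDesign, *, _rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Assign every gene a tissue, direction and planted response class.

    Class counts are round(n_genes * proportion); the rounding remainder
    goes to the background class (or the largest class when no background
    is planted). Assignment is a seeded permutation, so a given design is
    reproducible.
    """
    design.validate()
    rng = _rng if _rng is not None else np.random.default_rng(design.seed)
    props = {k: v for k, v in design.class_proportions.items() if v > 0}
    counts = {k: int(round(design.n_genes * v)) for k, v in props.items()}
    sink = "background" if "background" in counts else max(counts, key=counts.get)
    counts[sink] += design.n_genes - sum(counts.values())
    if counts[sink] < 0:
        raise ValueError("rounding produced a negative class count")

    labels = np.concatenate(
        [np.repeat(k, c) for k, c in counts.items()] or [np.array([], dtype=object)]
    )
    rng.shuffle(labels)
    tissue = np.where(
        rng.random(design.n_genes) < design.shoot_fraction, "shoot", "root"
    )
    gene_ids = [f"gene{str(i).zfill(len(str(design.n_genes)))}" for i in range(design.n_genes)]
    direction, cls = zip(*(split_class(l) for l in labels)) if design.n_genes else ((), ())
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "tissue": tissue,
            "direction": list(direction),
            "response_class": list(cls),
        }
    )


def _pattern_matrix(truth: pd.DataFrame, groups: tuple[str, ...], delta: float) -> np.ndarray:
    """Genes x groups matrix of multiplicative mean factors."""
    factors = np.ones((len(truth), len(groups)))
    gidx = {g: j for j, g in enumerate(groups)}
    cache: dict[tuple[str, str, str], dict[str, float]] = {}
    for i, (tis, d, c) in enumerate(
        zip(truth["tissue"], truth["direction"], truth["response_class"])
    ):
        if c == "background":
            continue
        key = (tis, d, c)
        if key not in cache:
            fn = expected_shoot_mean_pattern if tis == "shoot" else expected_mean_pattern
            cache[key] = fn(d, c, delta)
        for g, f in cache[key].items():
            if g in gidx:
                factors[i, gidx[g]] = f
    return factors


def simulate_counts(design: SimulationDesign) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw the count matrix and return it with the planted-truth table.

    The returned truth table carries an extra `base_mean` column (the
    baseline expression each gene's pattern multiplies) so tests and users
    can compare observed group means against the generating means.
    """
    design.validate()
    truth = plan_truth(design)
    rng = np.random.default_rng([design.seed, 1])

    lo, hi = design.base_mean_log_range
    baseline = 10.0 ** rng.uniform(lo, hi, size=design.n_genes)
    lengths = rng.integers(
        design.gene_length_range[0], design.gene_length_range[1] + 1, size=design.n_genes
    )

    n_samples = len(design.groups) * design.replicates
    if design.libsize_cv > 0:
        sigma = math.sqrt(math.log1p(design.libsize_cv**2))
        lib = np.exp(rng.normal(0.0, sigma, size=n_samples))
        lib /= np.exp(np.mean(np.log(lib)))  # geometric mean 1
    else:
        lib = np.ones(n_samples)

    factors = _pattern_matrix(truth, design.groups, design.effect_log2fc)
    group_idx = np.repeat(np.arange(len(design.groups)), design.replicates)
    mu = baseline[:, None] * factors[:, group_idx] * lib[None, :]

    if design.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / design.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))

    truth = truth.assign(base_mean=baseline)
    samples = design.sample_sheet()
    counts_df = pd.DataFrame(
        counts, index=truth["gene_id"].to_numpy(), columns=design.sample_names
    )
    counts_df.index.name = "gene_id"
    lengths_s = pd.Series(lengths, index=counts_df.index, name="length")
    return CountMatrix(counts=counts_df, samples=samples, gene_lengths=lengths_s), truth
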