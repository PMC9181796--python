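"""Set-algebra classification of recovery behaviour in a split-root design.

A deficiency-responsive gene "recovers" when the resupply contrast calls a
significant change in the opposite direction. Among recovered root genes,
the two split-half contrasts (resupplied half SPSR_R/S0_R, still-deprived
half SPS0_R/S0_R) separate:

  A/E local     — recovered only in the half resupplied with sulfate
  B/F systemic  — recovered only in the half left deficient (shoot-relayed)
  C/G both      — recovered in both halves (simultaneous local + systemic)
  D/H none      — recovered under whole-root resupply but in neither half

(A-D: genes up-regulated by deficiency; E-H: down-regulated.) In shoots the
homogeneous (SR_Sh/S0_Sh) and heterogeneous (SP_Sh/S0_Sh) resupply contrasts
split recovered genes into hetero-responsive (A/C) vs homogeneous-only
(B/D). Genes not recovered by the gating resupply contrast are labelled
'unrecovered'.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple

import pandas as pd

from .detest import DEGSet

ROOT_LABELS = {"A": "local", "B": "systemic", "C": "both", "D": "none",
               "E": "local", "F": "systemic", "G": "both", "H": "none"}
SHOOT_LABELS = {"A": "hetero_responsive", "B": "homo_only",
                "C": "hetero_responsive", "D": "homo_only"}


class ContrastSets(NamedTuple):
    """The up/down DEG sets of one contrast."""

    up: frozenset
    down: frozenset

    @classmethod
    def from_degsets(cls, up: DEGSet, down: DEGSet) -> "ContrastSets":
        return cls(up=frozenset(up.genes), down=frozenset(down.genes))


class RecoveredSets(NamedTuple):
    recovered_up: frozenset
    recovered_down: frozenset
    unrecovered_up: frozenset
    unrecovered_down: frozenset


def recovered_sets(deficiency: ContrastSets, full_resupply: ContrastSets) -> RecoveredSets:
    """Partition deficiency DEGs by whether resupply reversed them.

    recovered_up = deficiency.up intersected with full_resupply.down
    (genes induced by deficiency and significantly re-suppressed), and
    symmetrically for down; the complements are unrecovered.
    """
    r_up = deficiency.up & full_resupply.down
    r_down = deficiency.down & full_resupply.up
    return RecoveredSets(
        recovered_up=frozenset(r_up),
        recovered_down=frozenset(r_down),
        unrecovered_up=frozenset(deficiency.up - r_up),
        unrecovered_down=frozenset(deficiency.down - r_down),
    )


def _check_disjoint(cs: ContrastSets, name: str) -> None:
    overlap = cs.up & cs.down
    if overlap:
        raise ValueError(
            f"{name}: genes in both up and down sets: {sorted(overlap)[:5]}"
        )


def _rows(genes, tissue, direction, code, label):
    return [
        {"gene_id": g, "tissue": tissue, "direction": direction,
         "gene_set_code": code, "label": label}
        for g in sorted(genes)
    ]


def classify_root(
    deficiency: ContrastSets,
    sr_vs_s0: ContrastSets,
    spsr_vs_s0: ContrastSets,
    sps0_vs_s0: ContrastSets,
) -> pd.DataFrame:
    """Label every root deficiency DEG as local/systemic/both/none/unrecovered.

    Up branch, with R = deficiency.up & sr_vs_s0.down:
      A = R & spsr.down - sps0.down      (local)
      B = R & sps0.down - spsr.down      (systemic)
      C = R & spsr.down & sps0.down      (both)
      D = R - spsr.down - sps0.down      (none)
    The down branch (codes E-H) mirrors with contrast directions flipped.
    {A, B, C, D} partition R by construction.
    """
    for cs, nm in ((deficiency, "deficiency"), (sr_vs_s0, "SR/S0"),
                   (spsr_vs_s0, "SPSR/S0"), (sps0_vs_s0, "SPS0/S0")):
        _check_disjoint(cs, nm)
    rec = recovered_sets(deficiency, sr_vs_s0)

    rows: list[dict] = []
    for direction, r, unrec, half_a, half_b, codes in (
        ("up", rec.recovered_up, rec.unrecovered_up,
         spsr_vs_s0.down, sps0_vs_s0.down, "ABCD"),
        ("down", rec.recovered_down, rec.unrecovered_down,
         spsr_vs_s0.up, sps0_vs_s0.up, "EFGH"),
    ):
        both = r & half_a & half_b
        local = (r & half_a) - half_b
        systemic = (r & half_b) - half_a
        none = r - half_a - half_b
        for code, genes in zip(codes, (local, systemic, both, none)):
            rows.extend(_rows(genes, "root", direction, code, ROOT_LABELS[code]))
        rows.extend(_rows(unrec, "root", direction, "-", "unrecovered"))
    return pd.DataFrame(
        rows, columns=["gene_id", "tissue", "direction", "gene_set_code", "label"]
    )


def classify_shoot(
    deficiency: ContrastSets,
    sr_vs_s0: ContrastSets,
    sp_vs_s0: ContrastSets,
) -> pd.DataFrame:
    """Label shoot deficiency DEGs as hetero-responsive vs homogeneous-only.

    Up branch, with R = deficiency.up & sr_vs_s0.down (recovered under
    homogeneous resupply): A = R & sp_vs_s0.down (also recovered under
    heterogeneous resupply), B = R - sp_vs_s0.down. Down branch gives
    C and D symmetrically.
    """
    for cs, nm in ((deficiency, "deficiency"), (sr_vs_s0, "SR/S0"), (sp_vs_s0, "SP/S0")):
        _check_disjoint(cs, nm)
    rec = recovered_sets(deficiency, sr_vs_s0)

    rows: list[dict] = []
    for direction, r, unrec, sp_opposite, codes in (
        ("up", rec.recovered_up, rec.unrecovered_up, sp_vs_s0.down, "AB"),
        ("down", rec.recovered_down, rec.unrecovered_down, sp_vs_s0.up, "CD"),
    ):
        hetero = r & sp_opposite
        homo = r - sp_opposite
        for code, genes in zip(codes, (hetero, homo)):
            rows.extend(_rows(genes, "shoot", direction, code, SHOOT_LABELS[code]))
        rows.extend(_rows(unrec, "shoot", direction, "-", "unrecovered"))
    return pd.DataFrame(
        rows, columns=["gene_id", "tissue", "direction", "gene_set_code", "label"]
    )


def tissue_overlap(shoot_def: ContrastSets, root_def: ContrastSets) -> dict[str, int]:
    """Deficiency DEGs shared between tissues, per direction."""
    return {
        "up_common": len(shoot_def.up & root_def.up),
        "down_common": len(shoot_def.down & root_def.down),
        "up_shoot": len(shoot_def.up),
        "up_root": len(root_def.up),
        "down_shoot": len(shoot_def.down),
        "down_root": len(root_def.down),
    }


@dataclass(frozen=True)
class RecoverySummary:
    """A gene-set fraction with its presentation-ready rendering."""

    numerator: int
    denominator: int
    percentage: float
    rounded_text: str


def recovery_fraction(numerator: int, denominator: int, precision: int = 2) -> RecoverySummary:
    """Percentage numerator/denominator, rendered half-up at `precision` dp.

    Matches how set-size fractions are conventionally reported,
    e.g. recovery_fraction(128, 413) -> '30.99%'.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be non-negative")
    pct = 100.0 * numerator / denominator
    quant = Decimal(1).scaleb(-precision)
    text = str(
        (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
            quant, rounding=ROUND_HALF_UP
        )
    )
    return RecoverySummary(
        numerator=numerator, denominator=denominator, percentage=pct,
        rounded_text=f"{text}%",
    )


def set_sizes(labels: pd.DataFrame) -> dict[str, int]:
    """Cardinality of every labelled gene set, keyed '<tissue>.<direction>.<code>'."""
    out: dict[str, int] = {}
    for (tissue, direction, code), grp in labels.groupby(
        ["tissue", "direction", "gene_set_code"], sort=True
    ):
        key_code = code if code != "-" else "unrecovered"
        out[f"{tissue}.{direction}.{key_code}"] = len(grp)
    return out
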