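"""Instrument selection: significance filtering, greedy LD clumping,
F-statistic weak-instrument exclusion, and confounder screening.

The selection order is fixed — significance, clump, F, confounder — mirroring
the usual two-sample MR workflow: genome-wide (or locus-wide) significance
first, then pruning of correlated variants keeping the most significant per
clump, then exclusion of weak instruments (F < 10 by convention), and finally
removal of variants annotated to known confounder traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .summary_io import VariantAssociation


@dataclass
class LDMatrix:
    """Pairwise correlation (r) between variants, ordered as ``variant_ids``."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.variant_ids)
        if self.r.shape != (k, k):
            raise InputError(f"LD matrix shape {self.r.shape} does not match {k} variant ids")
        if not np.allclose(np.diag(self.r), 1.0):
            raise InputError("LD matrix diagonal must be 1")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise InputError("LD matrix must be symmetric")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def r2(self, a: str, b: str) -> float:
        try:
            return float(self.r[self._index[a], self._index[b]] ** 2)
        except KeyError as exc:
            raise InputError(f"variant {exc.args[0]} missing from LD matrix") from exc

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    @classmethod
    def identity(cls, variant_ids: Sequence[str]) -> "LDMatrix":
        return cls(list(variant_ids), np.eye(len(variant_ids)))

    @classmethod
    def from_tsv(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.r, index=self.variant_ids, columns=self.variant_ids).to_csv(
            path, sep="\t"
        )


@dataclass
class SelectionStep:
    step: str
    n_before: int
    n_after: int
    removed: list[str] = field(default_factory=list)
    detail: dict = field(default_factory=dict)


@dataclass
class InstrumentSet:
    """Selected instruments with per-variant F statistics and an ordered log
    of every filter applied and the variants it removed."""

    instruments: list[VariantAssociation]
    f_statistics: dict[str, float]
    selection_log: list[SelectionStep]

    @property
    def variant_ids(self) -> list[str]:
        return [r.variant_id for r in self.instruments]

    def log_dict(self) -> dict:
        return {
            "steps": [
                {
                    "step": s.step,
                    "n_before": s.n_before,
                    "n_after": s.n_after,
                    "removed": s.removed,
                    **({"detail": s.detail} if s.detail else {}),
                }
                for s in self.selection_log
            ],
            "n_selected": len(self.instruments),
        }


def filter_by_pvalue(
    records: Sequence[VariantAssociation], threshold: float
) -> list[VariantAssociation]:
    """Keep exactly the records with p-value strictly below ``threshold``,
    preserving input order."""
    if not (0 < threshold < 1):
        raise InputError(f"p-value threshold must be in (0,1), got {threshold}")
    return [r for r in records if r.pvalue < threshold]


def compute_f_statistic(beta: float, se: float) -> float:
    """Instrument strength as the squared z-score, F = (beta/se)^2.

    F < 10 conventionally flags a weak instrument.
    """
    if se <= 0:
        raise InputError(f"se must be positive, got {se}")
    return (beta / se) ** 2


def f_statistic_from_r2(r2: float, n: int) -> float:
    """Alternative F from variance explained: (n-2) * r2 / (1 - r2)."""
    if not (0 <= r2 < 1) or n < 3:
        raise InputError("need 0 <= r2 < 1 and n >= 3")
    return (n - 2) * r2 / (1 - r2)


def ld_clump(
    records: Sequence[VariantAssociation],
    ld: LDMatrix | None,
    r2_threshold: float,
    rank_by: str = "pvalue",
) -> list[VariantAssociation]:
    """Greedy clumping: repeatedly take the remaining record with the smallest
    p-value as an index variant and discard all remaining records whose
    squared correlation with it exceeds ``r2_threshold``.

    Ties in p-value are broken by variant_id, so the result is independent of
    the input ordering.  ``ld=None`` treats all variants as uncorrelated.
    The survivors are returned in input order.
    """
    if not (0 < r2_threshold <= 1):
        raise InputError(f"r2 threshold must be in (0,1], got {r2_threshold}")
    if rank_by != "pvalue":
        raise InputError("only p-value ranking is supported")
    if ld is None:
        return list(records)
    for r in records:
        if r.variant_id not in ld:
            raise InputError(f"variant {r.variant_id} missing from LD matrix")

    remaining = sorted(records, key=lambda r: (r.pvalue, r.variant_id))
    survivors: set[str] = set()
    while remaining:
        index = remaining.pop(0)
        survivors.add(index.variant_id)
        remaining = [
            r for r in remaining if ld.r2(index.variant_id, r.variant_id) <= r2_threshold
        ]
    return [r for r in records if r.variant_id in survivors]


def load_annotations(path) -> dict[str, set[str]]:
    """Two-column TSV (variant_id, trait), multiple rows per variant allowed."""
    df = pd.read_csv(path, sep="\t", header=0)
    out: dict[str, set[str]] = {}
    for vid, trait in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(str(vid), set()).add(str(trait))
    return out


def confounder_screen(
    records: Sequence[VariantAssociation],
    annotations: Mapping[str, set[str]] | None,
    blocked_traits: Sequence[str],
) -> tuple[list[VariantAssociation], list[dict]]:
    """Remove records annotated with any blocked trait (case-insensitive).

    Returns (kept, removals) where each removal records the triggering trait.
    """
    blocked = {t.lower() for t in blocked_traits}
    if not annotations or not blocked:
        return list(records), []
    kept, removals = [], []
    for r in records:
        hits = sorted(
            t for t in annotations.get(r.variant_id, ()) if t.lower() in blocked
        )
        if hits:
            removals.append({"variant_id": r.variant_id, "traits": hits})
        else:
            kept.append(r)
    return kept, removals


def select_instruments(
    records: Sequence[VariantAssociation],
    *,
    p_threshold: float,
    ld: LDMatrix | None = None,
    r2_threshold: float = 0.001,
    f_min: float | None = 10.0,
    annotations: Mapping[str, set[str]] | None = None,
    blocked_traits: Sequence[str] = (),
) -> InstrumentSet:
    """Run the full selection pipeline in fixed order:
    significance -> LD clump -> F filter -> confounder screen.

    ``f_min=None`` disables the weak-instrument filter.
    """
    log: list[SelectionStep] = []

    sig = filter_by_pvalue(records, p_threshold)
    sig_ids = {r.variant_id for r in sig}
    log.append(
        SelectionStep(
            "significance",
            len(records),
            len(sig),
            [r.variant_id for r in records if r.variant_id not in sig_ids],
            {"p_threshold": p_threshold},
        )
    )

    clumped = ld_clump(sig, ld, r2_threshold)
    clumped_ids = {r.variant_id for r in clumped}
    log.append(
        SelectionStep(
            "ld_clump",
            len(sig),
            len(clumped),
            [r.variant_id for r in sig if r.variant_id not in clumped_ids],
            {"r2_threshold": r2_threshold},
        )
    )

    fstats = {r.variant_id: compute_f_statistic(r.beta, r.se) for r in clumped}
    if f_min is not None:
        strong = [r for r in clumped if fstats[r.variant_id] >= f_min]
        log.append(
            SelectionStep(
                "f_filter",
                len(clumped),
                len(strong),
                [r.variant_id for r in clumped if fstats[r.variant_id] < f_min],
                {"f_min": f_min},
            )
        )
    else:
        strong = clumped

    kept, removals = confounder_screen(strong, annotations, blocked_traits)
    log.append(
        SelectionStep(
            "confounder_screen",
            len(strong),
            len(kept),
            [d["variant_id"] for d in removals],
            {"blocked_traits": list(blocked_traits), "removals": removals},
        )
    )

    return InstrumentSet(kept, {r.variant_id: fstats.get(r.variant_id, np.nan) for r in kept}, log)
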