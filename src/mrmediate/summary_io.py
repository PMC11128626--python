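"""Reading, validation and allele harmonization of GWAS summary statistics.

Two-sample Mendelian randomization combines per-variant effect estimates from
two independent GWAS.  Before any estimator can run, the exposure and outcome
effects for each shared variant must refer to the same effect allele; this
module implements the standard harmonization convention: align the outcome to
the exposure's effect allele, resolve strand flips by complementing, and treat
palindromic (A/T, C/G) variants explicitly because allele labels alone cannot
orient them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .errors import ConfigError, InputError

NUCLEOTIDES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Default column names, matching IEU OpenGWAS flat-file exports.
DEFAULT_COLUMNS: dict[str, str] = {
    "variant_id": "SNP",
    "chromosome": "chr",
    "position": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pval",
    "n": "samplesize",
}

MANDATORY_FIELDS = (
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pvalue",
)


@dataclass
class VariantAssociation:
    """One variant's summary association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele`` on the trait scale
    (log-odds for binary traits).
    """

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n: int | None = None

    def validate(self) -> None:
        if self.effect_allele not in NUCLEOTIDES or self.other_allele not in NUCLEOTIDES:
            raise InputError(
                f"{self.variant_id}: alleles must be single nucleotides, got "
                f"{self.effect_allele!r}/{self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise InputError(f"{self.variant_id}: effect and other allele are identical")
        if not (self.se > 0 and math.isfinite(self.se)):
            raise InputError(f"{self.variant_id}: se must be positive, got {self.se}")
        if not (0 < self.pvalue <= 1):
            raise InputError(f"{self.variant_id}: pvalue must be in (0,1], got {self.pvalue}")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise InputError(f"{self.variant_id}: eaf must be in (0,1), got {self.eaf}")
        if not math.isfinite(self.beta):
            raise InputError(f"{self.variant_id}: beta is not finite")

    @property
    def zscore(self) -> float:
        return self.beta / self.se

    def is_palindromic(self) -> bool:
        return COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass
class HarmonizedInstrument:
    """A variant with exposure and outcome effects on the same effect allele."""

    variant_id: str
    effect_allele: str
    other_allele: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf: float | None = None
    palindromic: bool = False
    action_taken: str = "kept"  # kept | flipped

    def validate(self) -> None:
        if self.se_exposure <= 0 or self.se_outcome <= 0:
            raise InputError(f"{self.variant_id}: harmonized SEs must be positive")


class ReadResult(NamedTuple):
    records: list[VariantAssociation]
    dropped: dict[str, int]  # reason -> count


def read_summary_table(
    path,
    column_map: Mapping[str, str] | None = None,
) -> ReadResult:
    """Read a tab-separated summary-statistic table.

    Rows violating the per-variant invariants (non-positive SE, p outside
    (0,1], bad alleles, out-of-range frequency) are dropped and counted in
    ``dropped`` by reason.  Allele fields are upper-cased before validation.

    Raises
    ------
    ConfigError
        if a mandatory mapped column is missing from the file.
    InputError
        if the table has no data rows.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)

    df = pd.read_csv(path, sep="\t", dtype={cols["chromosome"]: str})
    if df.empty:
        raise InputError(f"{path}: summary table contains no rows")

    missing = [cols[f] for f in MANDATORY_FIELDS if cols[f] not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing mandatory column(s) {missing}")

    has_eaf = cols["eaf"] in df.columns
    has_n = cols["n"] in df.columns

    records: list[VariantAssociation] = []
    dropped: dict[str, int] = {}
    for row in df.itertuples(index=False):
        r = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        try:
            eaf = r.get(cols["eaf"]) if has_eaf else None
            if eaf is not None and (isinstance(eaf, float) and math.isnan(eaf)):
                eaf = None
            n = r.get(cols["n"]) if has_n else None
            if n is not None and (isinstance(n, float) and math.isnan(n)):
                n = None
            rec = VariantAssociation(
                variant_id=str(r[cols["variant_id"]]),
                chromosome=str(r[cols["chromosome"]]),
                position=int(r[cols["position"]]),
                effect_allele=str(r[cols["effect_allele"]]).upper(),
                other_allele=str(r[cols["other_allele"]]).upper(),
                beta=float(r[cols["beta"]]),
                se=float(r[cols["se"]]),
                pvalue=float(r[cols["pvalue"]]),
                eaf=None if eaf is None else float(eaf),
                n=None if n is None else int(n),
            )
            rec.validate()
        except (InputError, ValueError, TypeError) as exc:
            reason = str(exc).split(",")[0][:80] or "invalid row"
            dropped[reason] = dropped.get(reason, 0) + 1
            continue
        records.append(rec)
    return ReadResult(records, dropped)


def associations_to_frame(records: Sequence[VariantAssociation]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


@dataclass
class HarmonizationResult:
    instruments: list[HarmonizedInstrument]
    dropped: list[dict] = field(default_factory=list)  # {"variant_id", "reason"}

    def drop_log_json(self) -> str:
        return json.dumps(
            {"n_kept": len(self.instruments), "n_dropped": len(self.dropped), "dropped": self.dropped},
            indent=2,
        )


def _aligned_outcome(exp: VariantAssociation, out: VariantAssociation):
    """Return (beta_outcome, eaf_outcome, flipped) with the outcome expressed
    on the exposure's effect allele, or None if the allele sets are
    irreconcilable even after strand complementing."""
    ea, oa = exp.effect_allele, exp.other_allele
    pairs = {
        (out.effect_allele, out.other_allele): False,
        (out.other_allele, out.effect_allele): True,
        (COMPLEMENT[out.effect_allele], COMPLEMENT[out.other_allele]): False,
        (COMPLEMENT[out.other_allele], COMPLEMENT[out.effect_allele]): True,
    }
    flipped = pairs.get((ea, oa))
    if flipped is None:
        return None
    beta = -out.beta if flipped else out.beta
    eaf = None
    if out.eaf is not None:
        eaf = 1.0 - out.eaf if flipped else out.eaf
    return beta, eaf, flipped


def harmonize(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    palindrome_policy: str = "infer",
    ambiguity_window: tuple[float, float] = (0.42, 0.58),
) -> HarmonizationResult:
    """Align outcome effects to the exposure's effect allele.

    For shared variants, swapped allele labels flip the outcome beta sign (and
    replace eaf by 1−eaf); strand-complement matches are resolved by
    complementing.  Palindromic variants are handled per ``palindrome_policy``:

    ``drop``
        always dropped.
    ``infer``
        oriented by allele frequency; dropped when either eaf is missing or
        falls inside ``ambiguity_window`` (frequency too close to 0.5 to call
        the strand).

    Variants absent from either table, or with irreconcilable allele sets, are
    dropped with the reason recorded — never silently kept.
    """
    if palindrome_policy not in ("drop", "infer"):
        raise ConfigError(f"unknown palindrome_policy {palindrome_policy!r}")
    if not exposure or not outcome:
        raise InputError("harmonize requires non-empty exposure and outcome tables")

    out_by_id = {r.variant_id: r for r in outcome}
    shared = [r for r in exposure if r.variant_id in out_by_id]
    if not shared:
        raise InputError("no shared variants between exposure and outcome")

    lo, hi = ambiguity_window
    kept: list[HarmonizedInstrument] = []
    dropped: list[dict] = []
    exp_ids = set()
    for exp in exposure:
        exp_ids.add(exp.variant_id)
        out = out_by_id.get(exp.variant_id)
        if out is None:
            dropped.append({"variant_id": exp.variant_id, "reason": "absent from outcome"})
            continue

        palindromic = exp.is_palindromic()
        if palindromic:
            if out.effect_allele not in (exp.effect_allele, exp.other_allele) or not out.is_palindromic():
                dropped.append({"variant_id": exp.variant_id, "reason": "irreconcilable alleles"})
                continue
            if palindrome_policy == "drop":
                dropped.append({"variant_id": exp.variant_id, "reason": "palindromic (policy=drop)"})
                continue
            if exp.eaf is None or out.eaf is None:
                dropped.append(
                    {"variant_id": exp.variant_id, "reason": "palindromic with missing eaf"}
                )
                continue
            # Align labels first, then use minor-allele concordance to detect
            # a strand flip that the labels cannot reveal.
            label_flip = out.effect_allele == exp.other_allele
            beta_o = -out.beta if label_flip else out.beta
            eaf_o = 1.0 - out.eaf if label_flip else out.eaf
            if lo <= exp.eaf <= hi or lo <= eaf_o <= hi:
                dropped.append(
                    {"variant_id": exp.variant_id, "reason": "palindromic with ambiguous eaf"}
                )
                continue
            freq_flip = (exp.eaf < 0.5) != (eaf_o < 0.5)
            if freq_flip:
                beta_o, eaf_o = -beta_o, 1.0 - eaf_o
            action = "flipped" if (label_flip != freq_flip) else "kept"
        else:
            aligned = _aligned_outcome(exp, out)
            if aligned is None:
                dropped.append({"variant_id": exp.variant_id, "reason": "irreconcilable alleles"})
                continue
            beta_o, _eaf_o, was_flipped = aligned
            action = "flipped" if was_flipped else "kept"

        inst = HarmonizedInstrument(
            variant_id=exp.variant_id,
            effect_allele=exp.effect_allele,
            other_allele=exp.other_allele,
            beta_exposure=exp.beta,
            se_exposure=exp.se,
            beta_outcome=beta_o,
            se_outcome=out.se,
            eaf=exp.eaf,
            palindromic=palindromic,
            action_taken=action,
        )
        inst.validate()
        kept.append(inst)

    for out_rec in outcome:
        if out_rec.variant_id not in exp_ids:
            dropped.append({"variant_id": out_rec.variant_id, "reason": "absent from exposure"})

    return HarmonizationResult(kept, dropped)


def instruments_to_frame(instruments: Iterable[HarmonizedInstrument]) -> pd.DataFrame:
    return pd.DataFrame([asdict(i) for i in instruments])


def write_instruments_tsv(instruments: Iterable[HarmonizedInstrument], path) -> None:
    instruments_to_frame(instruments).to_csv(path, sep="\t", index=False)
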