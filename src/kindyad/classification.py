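"""Kin classification of male dyads and its validation.

Two cutoff procedures convert a dyad's relatedness estimate r into a
"related" / "unrelated" decision at the half-sibling level:

* **A1** — empirical rule: keep the top ``retain_fraction`` (default 85%) of
  the r distribution of *known* half-sibling dyads; the threshold is the
  (1 - retain_fraction) quantile. Every dyad is labelled related
  (r >= threshold, boundary inclusive) or unrelated.
* **A2** — simulation rule: the related threshold is the lower-tail
  (default 5%) quantile of r simulated for half-sibling dyads, the
  unrelated threshold the upper-tail quantile of r simulated for unrelated
  dyads. Dyads strictly above the first are related, strictly below the
  second unrelated, and those in between are left unassigned (the exclusion
  zone). Boundaries are exclusive.

Quantiles use linear interpolation between order statistics throughout;
cutoffs are sensitive to this convention, so it is fixed here.

Also provided: the validation accounting for a set of known-related dyads,
per-spell kin/peer co-residence flags for the demographic records, and the
Mendelian compatibility check used to confirm maternal half-sibships.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .residence import MaleResidenceRecord

__all__ = [
    "CutoffRule",
    "ValidationReport",
    "a1_cutoff",
    "a2_cutoffs",
    "classify",
    "classify_table",
    "validate",
    "kin_presence_flags",
    "mendelian_check",
]


@dataclass(frozen=True)
class CutoffRule:
    """Classification thresholds; ``unrelated_threshold`` is A2-only."""

    kind: str  # "A1" or "A2"
    related_threshold: float
    unrelated_threshold: Optional[float] = None
    source_percentiles: Optional[dict] = None

    def __post_init__(self):
        if self.kind not in ("A1", "A2"):
            raise ValueError("kind must be 'A1' or 'A2'")
        if not np.isfinite(self.related_threshold):
            raise ValueError("related_threshold must be finite")
        if self.kind == "A2":
            if self.unrelated_threshold is None or not np.isfinite(self.unrelated_threshold):
                raise ValueError("A2 rule needs a finite unrelated_threshold")


@dataclass
class ValidationReport:
    """Classification outcome counts for a set of known-related dyads."""

    n_total: int
    n_correct: int
    n_incorrect: int
    n_unassigned: int
    pct_correct: float
    pct_incorrect: float
    pct_unassigned: float


def _pct(count: int, total: int) -> float:
    """Percentage with 2-decimal half-up rounding."""
    raw = Decimal(count * 100) / Decimal(total)
    return float(raw.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def a1_cutoff(known_related_r: Sequence[float],
              retain_fraction: float = 0.85) -> CutoffRule:
    """Empirical cutoff retaining the top ``retain_fraction`` of known-kin r.

    The threshold is the (1 - retain_fraction) linear-interpolation quantile
    of the observed distribution, so 85% of the known related dyads sit at
    or above it.
    """
    r = np.asarray(list(known_related_r), dtype=float)
    if len(r) < 10:
        raise ValueError(f"need >= 10 known related r-values, got {len(r)}")
    if not (0.0 < retain_fraction < 1.0):
        raise ValueError("retain_fraction must lie in (0, 1)")
    thr = float(np.quantile(r, 1.0 - retain_fraction))
    return CutoffRule("A1", thr,
                      source_percentiles={"retain_fraction": retain_fraction})


def a2_cutoffs(sim_related_r: Sequence[float], sim_unrelated_r: Sequence[float],
               tail: float = 0.05) -> CutoffRule:
    """Dual cutoffs from simulated related and unrelated r distributions.

    related_threshold = ``tail`` quantile of the related simulations;
    unrelated_threshold = (1 - tail) quantile of the unrelated simulations.
    If the exclusion zone is empty or inverted (related_threshold below
    unrelated_threshold) a warning is emitted but the rule is returned.
    """
    rel = np.asarray(list(sim_related_r), dtype=float)
    unr = np.asarray(list(sim_unrelated_r), dtype=float)
    if len(rel) < 100 or len(unr) < 100:
        raise ValueError("need >= 100 simulated r-values per distribution")
    if not (0.0 < tail < 0.5):
        raise ValueError("tail must lie in (0, 0.5)")
    rel_thr = float(np.quantile(rel, tail))
    unr_thr = float(np.quantile(unr, 1.0 - tail))
    if rel_thr <= unr_thr:
        warnings.warn(
            f"A2 exclusion zone empty or inverted: related_threshold "
            f"{rel_thr:.4f} <= unrelated_threshold {unr_thr:.4f}")
    return CutoffRule("A2", rel_thr, unr_thr,
                      source_percentiles={"tail": tail})


def classify(r: float, rule: CutoffRule) -> str:
    """Label a dyad 'related', 'unrelated' or (A2 only) 'unassigned'.

    A2 labels a dyad related only when r clears *both* thresholds (strictly
    above the related cutoff, not below the unrelated one), and unrelated
    only when it falls below both. With the usual non-inverted rule this is
    exactly "above the related cutoff" / "below the unrelated cutoff"; when
    the exclusion zone is inverted the ambiguous band is left unassigned,
    which keeps the false-positive guarantee of the unrelated-tail cutoff.
    """
    if rule.kind == "A1":
        return "related" if r >= rule.related_threshold else "unrelated"
    if r > rule.related_threshold and r >= rule.unrelated_threshold:
        return "related"
    if r < rule.unrelated_threshold and r <= rule.related_threshold:
        return "unrelated"
    return "unassigned"


def classify_table(dyads: pd.DataFrame, rule: CutoffRule) -> pd.DataFrame:
    """Apply a rule to a dyad table with an ``r`` column; adds label columns."""
    out = dyads.copy()
    out["label"] = [classify(r, rule) for r in out["r"]]
    out["rule_kind"] = rule.kind
    out["related_threshold"] = rule.related_threshold
    out["unrelated_threshold"] = rule.unrelated_threshold
    return out


def validate(labels: Sequence[str]) -> ValidationReport:
    """Score labels for dyads that are all truly related.

    'related' counts as correct, 'unrelated' as incorrect, 'unassigned' as
    excluded; rates are percentages rounded half-up to 2 decimals.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("no labels to validate")
    n = len(labels)
    n_correct = sum(1 for l in labels if l == "related")
    n_incorrect = sum(1 for l in labels if l == "unrelated")
    n_unassigned = sum(1 for l in labels if l == "unassigned")
    if n_correct + n_incorrect + n_unassigned != n:
        raise ValueError("labels contain unknown values")
    return ValidationReport(
        n_total=n, n_correct=n_correct, n_incorrect=n_incorrect,
        n_unassigned=n_unassigned,
        pct_correct=_pct(n_correct, n),
        pct_incorrect=_pct(n_incorrect, n),
        pct_unassigned=_pct(n_unassigned, n),
    )


# ---------------------------------------------------------------------------
# Kin/peer co-residence flags

def _related_pairs(classified_dyads: pd.DataFrame) -> set:
    pairs = set()
    for _, row in classified_dyads.iterrows():
        if row["label"] == "related":
            pairs.add(frozenset((row["id1"], row["id2"])))
    return pairs


def kin_presence_flags(classified_dyads: pd.DataFrame,
                       residence: Sequence[MaleResidenceRecord],
                       window_months: int = 3) -> list:
    """Attach kin/peer co-residence flags to residence spells.

    For each spell: ``kin_at_entry`` — a classified-related male was
    resident in the same group at the entry month; ``kin_3mo`` — a related
    male was co-resident at some point within ``window_months`` after entry
    (entry itself included); ``peer_at_entry`` — a male from the same natal
    group born within 2 years was resident at entry;
    ``coresidence_fraction`` — fraction of the spell with >= 1 related male
    co-resident. Raises on overlapping spells of the same male in the same
    group.
    """
    recs = list(residence)
    for r in recs:
        if r.entry_month > r.exit_month:
            raise ValueError(f"{r.male_id}: entry after exit")
    by_male_group: dict = {}
    for r in recs:
        by_male_group.setdefault((r.male_id, r.group_id), []).append(r)
    for (male, group), spells in by_male_group.items():
        spells = sorted(spells, key=lambda s: s.entry_month)
        for a, b in zip(spells, spells[1:]):
            if b.entry_month < a.exit_month:
                raise ValueError(
                    f"overlapping spells for male {male} in group {group}")
    related = _related_pairs(classified_dyads)
    out = []
    for r in recs:
        kin_entry = False
        kin_win = False
        peer_entry = False
        intervals = []
        for o in recs:
            if o is r or o.group_id != r.group_id or o.male_id == r.male_id:
                continue
            overlaps_entry = o.entry_month <= r.entry_month < o.exit_month
            if frozenset((r.male_id, o.male_id)) in related:
                if overlaps_entry:
                    kin_entry = True
                # co-resident (both present) at some month within
                # [entry, entry + window]
                overlap = (o.entry_month < r.exit_month
                           and o.exit_month > r.entry_month)
                if overlap and o.entry_month <= r.entry_month + window_months:
                    kin_win = True
                lo = max(r.entry_month, o.entry_month)
                hi = min(r.exit_month, o.exit_month)
                if hi > lo:
                    intervals.append((lo, hi))
            if overlaps_entry and _is_peer(r, o):
                peer_entry = True
        frac = _union_length(intervals) / r.duration_months
        out.append(replace(r, kin_at_entry=kin_entry, kin_3mo=kin_win,
                           peer_at_entry=peer_entry,
                           coresidence_fraction=min(1.0, frac)))
    return out


def _is_peer(a: MaleResidenceRecord, b: MaleResidenceRecord) -> bool:
    if a.natal_group is None or b.natal_group is None:
        return False
    if a.birth_year is None or b.birth_year is None:
        return False
    return a.natal_group == b.natal_group and abs(a.birth_year - b.birth_year) <= 2


def _union_length(intervals: list) -> float:
    total = 0.0
    last_hi = None
    for lo, hi in sorted(intervals):
        if last_hi is None or lo >= last_hi:
            total += hi - lo
            last_hi = hi
        elif hi > last_hi:
            total += hi - last_hi
            last_hi = hi
    return total


# ---------------------------------------------------------------------------
# Mendelian compatibility

def mendelian_check(offspring: dict, mother: dict,
                    max_mismatch: int = 1) -> tuple:
    """Mother-offspring compatibility over shared non-missing loci.

    A locus mismatches when the offspring shares no allele with the mother.
    Returns ``(compatible, n_mismatches)``; compatible iff mismatches <=
    ``max_mismatch`` (default 1, tolerating a single genotyping error or
    null allele).
    """
    shared = [loc for loc in offspring
              if offspring.get(loc) is not None and mother.get(loc) is not None]
    if not shared:
        raise ValueError("no shared non-missing loci")
    mismatches = sum(
        1 for loc in shared if not set(offspring[loc]) & set(mother[loc]))
    return mismatches <= max_mismatch, mismatches
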