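"""Exposure-instrument panel handling: load, validate, proxy, harmonize.

The instrument panel is the set of SNPs robustly associated with the
exposure (here, leukocyte telomere length) in an external GWAS.  Per-allele
effects are expressed in SD of the exposure per copy of the effect allele,
and the harmonization convention fixes the effect allele as the one
associated with a *longer* telomere, so harmonized effects are positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "InstrumentRecord",
    "InstrumentPanel",
    "PanelValidationError",
    "DEFAULT_PROXY_WHITELIST",
    "load_summary_stats",
    "filter_gw_significant",
    "substitute_proxy",
    "harmonize_alleles",
    "hwe_exact_test",
    "effect_allele_freq",
]

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: proxy r2 exceptions accepted below the 0.9 rule, keyed by proxy rsid
DEFAULT_PROXY_WHITELIST = {"rs55749605": 0.84, "rs7705526": 0.79}


class PanelValidationError(ValueError):
    """Raised when summary-statistic rows violate panel invariants."""


@dataclass(frozen=True)
class InstrumentRecord:
    rsid: str
    effect_allele: str
    other_allele: str
    beta_x: float          # SD exposure per effect-allele copy
    se_x: float
    pval: float
    eaf: Optional[float] = None   # effect-allele frequency in the GWAS
    proxy_of: Optional[str] = None
    proxy_r2: Optional[float] = None

    def __post_init__(self):
        if self.effect_allele not in _VALID_ALLELES or self.other_allele not in _VALID_ALLELES:
            raise PanelValidationError(
                f"{self.rsid}: alleles must be single bases in ACGT")
        if self.effect_allele == self.other_allele:
            raise PanelValidationError(f"{self.rsid}: alleles identical")
        if not (self.se_x > 0):
            raise PanelValidationError(f"{self.rsid}: non-positive SE {self.se_x}")
        if not (0.0 <= self.pval <= 1.0):
            raise PanelValidationError(f"{self.rsid}: p-value outside [0,1]")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            raise PanelValidationError(f"{self.rsid}: eaf outside (0,1)")
        if self.proxy_r2 is not None and not (0.0 <= self.proxy_r2 <= 1.0):
            raise PanelValidationError(f"{self.rsid}: proxy r2 outside [0,1]")

    def is_ambiguous(self) -> bool:
        """A/T or C/G pairs cannot be strand-resolved from alleles alone."""
        return _COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass(frozen=True)
class InstrumentPanel:
    records: tuple
    provenance: str = ""
    selection_threshold: float = 5e-8

    def __post_init__(self):
        object.__setattr__(self, "records", tuple(self.records))
        rsids = [r.rsid for r in self.records]
        dupes = {r for r in rsids if rsids.count(r) > 1}
        if dupes:
            raise PanelValidationError(f"duplicate rsids in panel: {sorted(dupes)}")

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def rsids(self) -> list[str]:
        return [r.rsid for r in self.records]

    def get(self, rsid: str) -> InstrumentRecord:
        for r in self.records:
            if r.rsid == rsid:
                return r
        raise KeyError(rsid)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


_DEFAULT_COLUMNS = {
    "rsid": "rsid", "effect_allele": "effect_allele",
    "other_allele": "other_allele", "beta": "beta", "se": "se",
    "pval": "pval", "eaf": "eaf",
}


def load_summary_stats(
    path,
    column_map: Mapping[str, str] | None = None,
    sep: str = "\t",
    provenance: str = "",
) -> InstrumentPanel:
    """Read an exposure summary-statistic table into a validated panel.

    ``column_map`` maps the canonical names (rsid, effect_allele,
    other_allele, beta, se, pval, eaf) onto the file's column headers, so
    GWAS-SSF-style exports load without renaming.  Rows violating record
    invariants are reported together with their 1-based data line numbers.
    """
    cols = dict(_DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep=sep)
    required = ["rsid", "effect_allele", "other_allele", "beta", "se", "pval"]
    missing = [cols[k] for k in required if cols[k] not in df.columns]
    if missing:
        raise PanelValidationError(f"missing required column(s): {missing}")
    has_eaf = cols["eaf"] in df.columns

    records, errors = [], []
    for i, row in df.iterrows():
        line = i + 1
        try:
            records.append(InstrumentRecord(
                rsid=str(row[cols["rsid"]]),
                effect_allele=str(row[cols["effect_allele"]]).upper(),
                other_allele=str(row[cols["other_allele"]]).upper(),
                beta_x=float(row[cols["beta"]]),
                se_x=float(row[cols["se"]]),
                pval=float(row[cols["pval"]]),
                eaf=float(row[cols["eaf"]]) if has_eaf and pd.notna(row[cols["eaf"]]) else None,
            ))
        except (PanelValidationError, ValueError) as exc:
            errors.append(f"line {line}: {exc}")
    rsids = [r.rsid for r in records]
    for rs in sorted(set(rsids)):
        if rsids.count(rs) > 1:
            lines = [i + 1 for i, r in enumerate(records) if r.rsid == rs]
            errors.append(f"duplicate rsid {rs} on data lines {lines}")
    if errors:
        raise PanelValidationError("; ".join(errors))
    return InstrumentPanel(records=tuple(records), provenance=provenance)


def filter_gw_significant(
    panel: InstrumentPanel, threshold: float = 5e-8
) -> InstrumentPanel:
    """Keep instruments with p strictly below the genome-wide threshold."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    kept = tuple(r for r in panel if r.pval < threshold)
    return InstrumentPanel(records=kept, provenance=panel.provenance,
                           selection_threshold=threshold)


def substitute_proxy(
    panel: InstrumentPanel,
    missing_rsid: str,
    proxy_record: InstrumentRecord,
    r2: float,
    whitelist: Mapping[str, float] | None = None,
) -> InstrumentPanel:
    """Replace an unavailable instrument with an LD proxy.

    A proxy is accepted when its LD with the index SNP is r2 >= 0.9, or when
    the proxy rsid appears on the explicit exception whitelist (two such
    exceptions ship as :data:`DEFAULT_PROXY_WHITELIST`).  The replacement
    record carries ``proxy_of`` and ``proxy_r2`` provenance.
    """
    if whitelist is None:
        whitelist = DEFAULT_PROXY_WHITELIST
    if missing_rsid not in panel.rsids:
        raise KeyError(f"{missing_rsid} not in panel")
    if proxy_record.rsid in panel.rsids:
        raise PanelValidationError(
            f"proxy {proxy_record.rsid} already present in panel")
    if not (r2 >= 0.9 or proxy_record.rsid in whitelist):
        raise PanelValidationError(
            f"proxy {proxy_record.rsid} for {missing_rsid} rejected: "
            f"r2={r2} < 0.9 and not whitelisted")
    new = replace(proxy_record, proxy_of=missing_rsid, proxy_r2=r2)
    records = tuple(new if r.rsid == missing_rsid else r for r in panel)
    return InstrumentPanel(records=records, provenance=panel.provenance,
                           selection_threshold=panel.selection_threshold)


def harmonize_alleles(
    panel: InstrumentPanel,
    cohort_alleles: pd.DataFrame,
    ambiguity_band: tuple[float, float] = (0.42, 0.58),
) -> tuple[InstrumentPanel, pd.DataFrame]:
    """Align the cohort's dosage allele coding to the panel's effect allele.

    ``cohort_alleles`` needs columns ``rsid``, ``counted_allele`` (the allele
    the dosage column counts) and ``other_allele``; an optional ``eaf``
    column carries the cohort effect-allele frequency used to resolve
    strand-ambiguous SNPs.

    Per SNP one action is logged:

    * ``match`` — cohort counts the effect allele; nothing to do.
    * ``swap`` — cohort counts the other allele; downstream dosage must be
      recoded ``2 - g`` (``flip_dosage`` is True).
    * ``strand_flip`` / ``strand_flip_swap`` — alleles reconcile only after
      Watson–Crick complementing; same dosage rule as match/swap.
    * ``drop`` — alleles irreconcilable, or strand-ambiguous (A/T, C/G)
      without frequency evidence, or ambiguous with frequency inside the
      ``ambiguity_band``.

    Returns the panel restricted to retained SNPs plus the action log.
    """
    info = cohort_alleles.set_index("rsid")
    kept, log = [], []

    def entry(rsid, action, flip, note=""):
        log.append({"rsid": rsid, "action": action,
                    "flip_dosage": flip, "note": note})

    for rec in panel:
        if rec.rsid not in info.index:
            entry(rec.rsid, "drop", False, "absent from cohort")
            continue
        row = info.loc[rec.rsid]
        counted = str(row["counted_allele"]).upper()
        other = str(row["other_allele"]).upper()
        cohort_eaf = float(row["eaf"]) if "eaf" in info.columns and pd.notna(row.get("eaf")) else None

        if rec.is_ambiguous():
            action = _resolve_ambiguous(rec, counted, other, cohort_eaf, ambiguity_band)
            if action is None:
                entry(rec.rsid, "drop", False, "strand-ambiguous, unresolved")
                continue
        elif (counted, other) == (rec.effect_allele, rec.other_allele):
            action = "match"
        elif (counted, other) == (rec.other_allele, rec.effect_allele):
            action = "swap"
        elif (_COMPLEMENT[counted], _COMPLEMENT[other]) == (rec.effect_allele, rec.other_allele):
            action = "strand_flip"
        elif (_COMPLEMENT[counted], _COMPLEMENT[other]) == (rec.other_allele, rec.effect_allele):
            action = "strand_flip_swap"
        else:
            entry(rec.rsid, "drop", False,
                  f"irreconcilable alleles {counted}/{other} vs "
                  f"{rec.effect_allele}/{rec.other_allele}")
            continue
        flip = action in ("swap", "strand_flip_swap")
        entry(rec.rsid, action, flip)
        kept.append(rec)

    harmonized = InstrumentPanel(records=tuple(kept), provenance=panel.provenance,
                                 selection_threshold=panel.selection_threshold)
    return harmonized, pd.DataFrame(log, columns=["rsid", "action", "flip_dosage", "note"])


def _resolve_ambiguous(rec, counted, other, cohort_eaf, band):
    """Frequency-based orientation for A/T and C/G SNPs; None means drop."""
    if {counted, other} != {rec.effect_allele, rec.other_allele}:
        return None
    if rec.eaf is None or cohort_eaf is None:
        return None
    lo, hi = band
    if lo <= rec.eaf <= hi or lo <= cohort_eaf <= hi:
        return None  # frequencies too close to 0.5 to orient
    same_side = (rec.eaf < 0.5) == (cohort_eaf < 0.5)
    if counted == rec.effect_allele:
        # counting the effect-allele letter: frequency should match the
        # panel's eaf; opposite sides imply the opposite strand (and so the
        # other allele) is being counted.
        return "match" if same_side else "strand_flip_swap"
    return "strand_flip" if same_side else "swap"


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy–Weinberg test on genotype counts.

    Conditional on the allele counts, the heterozygote count under HWE
    follows the distribution of Levene/Haldane; the two-sided p-value sums
    the probabilities of all heterozygote counts no more probable than the
    observed one.  Computed in log space so large samples are exact to
    floating precision.
    """
    counts = (n_AA, n_Aa, n_aa)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise ValueError("at least one genotype count must be positive")
    n_a = 2 * n_AA + n_Aa  # count of A alleles
    n_b = 2 * n_aa + n_Aa
    rare = min(n_a, n_b)
    # heterozygote counts share the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    log_probs = np.array([_log_hwe_prob(h, n_a, n_b, n) for h in hets])
    log_probs -= _logsumexp(log_probs)
    obs = log_probs[np.flatnonzero(hets == n_Aa)[0]]
    include = log_probs <= obs + 1e-12
    return float(min(1.0, math.exp(_logsumexp(log_probs[include]))))


def _log_hwe_prob(n_het, n_a, n_b, n):
    n_AA = (n_a - n_het) // 2
    n_aa = (n_b - n_het) // 2
    lg = math.lgamma
    return (lg(n + 1) - lg(n_AA + 1) - lg(n_het + 1) - lg(n_aa + 1)
            + n_het * math.log(2) + lg(n_a + 1) + lg(n_b + 1) - lg(2 * n + 1))


def _logsumexp(a):
    m = np.max(a)
    return float(m + np.log(np.sum(np.exp(a - m))))


def effect_allele_freq(dosages: Iterable[float]) -> float:
    """Effect-allele frequency from dosages on [0, 2]: mean/2 over observed."""
    arr = np.asarray(list(dosages) if not isinstance(dosages, (np.ndarray, pd.Series)) else dosages,
                     dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("no observed dosages")
    if np.any((arr < 0) | (arr > 2)):
        raise ValueError("dosages must lie in [0, 2]")
    return float(arr.mean() / 2.0)
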