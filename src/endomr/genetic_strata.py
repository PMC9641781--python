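"""Analysis strata: APOE-e4 carrier status and polygenic-risk groups.

APOE haplotypes (e2/e3/e4) are resolved from the rs429358 and rs7412
genotypes with the standard map (rs429358-T/rs7412-T -> e2, T/C -> e3,
C/C -> e4).  Carriers of at least one e4 allele form one stratum,
non-carriers the other; e2/e4 heterozygotes are excluded from analysis
because the two alleles' opposite risk effects make the genotype
uninterpretable in a carrier dichotomy.

Genetic predisposition strata come from a weighted polygenic risk score
(sum of risk-allele dosages times per-allele log-odds weights),
z-standardized within the cohort and split at its 75th percentile.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

__all__ = ["ApoeCall", "PrsResult", "classify_apoe", "compute_prs",
           "split_prs_groups", "build_strata"]

# haplotype -> (rs429358 allele, rs7412 allele)
_HAPLOTYPE_ALLELES = {"e2": ("T", "T"), "e3": ("T", "C"), "e4": ("C", "C")}


@dataclass(frozen=True)
class ApoeCall:
    rs429358: str
    rs7412: str
    epsilon_pair: str
    e4_carrier: bool
    excluded: bool


@dataclass
class PrsResult:
    raw: pd.Series
    z: pd.Series
    group: pd.Series       # "high" | "low"
    percentile: float
    threshold: float       # raw-score value at the percentile


def _sorted_genotype(g: str) -> tuple[str, str]:
    g = g.strip().upper().replace("/", "")
    if len(g) != 2 or any(a not in "CT" for a in g):
        raise ValueError(f"APOE genotype must be two alleles from C/T, got {g!r}")
    return tuple(sorted(g))


def classify_apoe(g429358: str, g7412: str) -> ApoeCall:
    """Resolve the APOE epsilon genotype from the two coding SNPs.

    The double heterozygote (C/T at both SNPs) is phase-ambiguous between
    e2/e4 and e1/e3; following the convention that e1 is absent, it is
    called e2/e4 and flagged ``excluded``.
    """
    a = _sorted_genotype(g429358)
    b = _sorted_genotype(g7412)
    key = (a, b)
    table = {
        (("T", "T"), ("T", "T")): ("e2", "e2"),
        (("T", "T"), ("C", "T")): ("e2", "e3"),
        (("T", "T"), ("C", "C")): ("e3", "e3"),
        (("C", "T"), ("T", "T")): ("e1", "e2"),   # requires the rare e1 haplotype
        (("C", "T"), ("C", "T")): ("e2", "e4"),   # no-e1 convention
        (("C", "T"), ("C", "C")): ("e3", "e4"),
        (("C", "C"), ("T", "T")): ("e1", "e1"),
        (("C", "C"), ("C", "T")): ("e1", "e4"),
        (("C", "C"), ("C", "C")): ("e4", "e4"),
    }
    pair = table[key]
    if "e1" in pair:
        raise ValueError(
            f"genotype rs429358={g429358}, rs7412={g7412} implies the e1 "
            "haplotype, which this classifier assumes absent")
    label = "/".join(pair)
    e4 = "e4" in pair
    excluded = pair == ("e2", "e4")
    return ApoeCall(rs429358="".join(a), rs7412="".join(b),
                    epsilon_pair=label, e4_carrier=e4, excluded=excluded)


def compute_prs(dosages: pd.DataFrame, weights: pd.Series) -> PrsResult:
    """Weighted allele sum, z-standardized within the cohort.

    ``weights`` must be indexed by rsid and aligned to dosage columns after
    harmonization to the risk-increasing allele.  Group labels are filled
    in by :func:`split_prs_groups`; here they are left empty.
    """
    missing = [r for r in weights.index if r not in dosages.columns]
    extra = [c for c in dosages.columns if c not in weights.index]
    if missing or extra:
        raise ValueError(f"rsid mismatch between dosages and weights: "
                         f"missing={missing}, unweighted={extra}")
    if not np.all(np.isfinite(weights.to_numpy(dtype=float))):
        raise ValueError("non-finite PRS weight")
    raw = dosages[list(weights.index)].to_numpy(dtype=float) @ weights.to_numpy(dtype=float)
    raw = pd.Series(raw, index=dosages.index, name="prs_raw")
    sd = raw.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate PRS: all scores identical")
    z = ((raw - raw.mean()) / sd).rename("prs_z")
    return PrsResult(raw=raw, z=z, group=pd.Series(index=raw.index, dtype=object),
                     percentile=np.nan, threshold=np.nan)


def split_prs_groups(scores: pd.Series, percentile: float = 75.0) -> pd.Series:
    """High/low predisposition split at a cohort percentile of the score.

    The threshold is the linear-interpolation quantile of the scores;
    individuals strictly above it are ``high``, all others ``low`` (so ties
    at the threshold fall in the low group).
    """
    s = pd.Series(scores, dtype=float)
    if len(s) < 4:
        raise ValueError("need at least 4 individuals to split")
    if s.std(ddof=0) == 0:
        raise ValueError("all scores identical: percentile split undefined")
    thr = float(np.percentile(s.to_numpy(), percentile, method="linear"))
    labels = pd.Series(np.where(s > thr, "high", "low"), index=s.index, name="prs_group")
    if (labels == "high").sum() == 0:
        warnings.warn("no individual strictly above the percentile threshold; "
                      "all labeled low", stacklevel=2)
    return labels


def build_strata(
    apoe_genotypes: pd.DataFrame,
    prs_dosages: pd.DataFrame,
    prs_weights: pd.Series,
    percentile: float = 75.0,
) -> pd.DataFrame:
    """Assemble the per-individual strata table.

    ``apoe_genotypes`` needs columns ``rs429358`` and ``rs7412`` (genotype
    strings).  Returns a frame indexed like the inputs with columns
    ``apoe_e4`` (0/1), ``apoe_excluded`` (bool, e2/e4), ``prs_z`` and
    ``prs_group``.
    """
    calls = [classify_apoe(r, s) for r, s in
             zip(apoe_genotypes["rs429358"], apoe_genotypes["rs7412"])]
    prs = compute_prs(prs_dosages, prs_weights)
    return pd.DataFrame({
        "apoe_e4": [int(c.e4_carrier) for c in calls],
        "apoe_excluded": [c.excluded for c in calls],
        "epsilon_pair": [c.epsilon_pair for c in calls],
        "prs_z": prs.z,
        "prs_group": split_prs_groups(prs.z, percentile=percentile),
    }, index=apoe_genotypes.index)
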