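"""Accurate-mass matching: internal-standard location and putative annotation.

All matching is level-4 putative, by mass alone, within a ppm tolerance
(default ±5 ppm).  Adduct m/z values are computed from the neutral
monoisotopic mass and a fixed table of adduct mass shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import PeakMatrix, FeatureInfo

__all__ = ["ISConfig", "AdductRule", "ADDUCT_RULES", "ppm_error",
           "find_internal_standard", "annotate_features", "strip_is_features"]

# particle / adduct mass shifts (Da), from CODATA / standard atomic masses
PROTON = 1.007276
C13_SPACING = 1.00336


@dataclass(frozen=True)
class AdductRule:
    """An adduct: observed m/z = neutral monoisotopic mass + ``mass_shift``."""

    label: str
    mass_shift: float
    polarity: str


#: Adduct set used for putative annotation: [M+H]+, [M+Na]+, [M+NH4]+ in
#: positive mode; [M−H]−, [M+Cl]−, [M+Hac−H]− (acetate) in negative mode.
ADDUCT_RULES: list[AdductRule] = [
    AdductRule("[M+H]+", 1.007276, "positive"),
    AdductRule("[M+Na]+", 22.989218, "positive"),
    AdductRule("[M+NH4]+", 18.033823, "positive"),
    AdductRule("[M-H]-", -1.007276, "negative"),
    AdductRule("[M+Cl]-", 34.969402, "negative"),
    AdductRule("[M+Hac-H]-", 59.013851, "negative"),
]


@dataclass
class ISConfig:
    """Internal-standard identity and screening parameters.

    ``expected_mz`` is the m/z of the protonated ([M+H]+) or deprotonated
    ([M−H]−) internal standard; ``k_qc``/``k_study`` are the MAD multipliers
    applied to intrastudy QCs and study samples during outlier screening.
    """

    name: str = "L-tryptophan-d5"
    expected_mz: float = 210.12297
    polarity: str = "positive"
    ppm_tol: float = 5.0
    k_qc: float = 3.0
    k_study: float = 2.0

    def __post_init__(self) -> None:
        if self.ppm_tol <= 0 or self.k_qc <= 0 or self.k_study <= 0:
            raise ValueError("ppm_tol and MAD multipliers must be positive")


def ppm_error(observed_mz: float, reference_mz: float) -> float:
    """Signed mass error in parts-per-million:
    ``(observed − reference) / reference × 1e6``."""
    if np.any(np.asarray(observed_mz) <= 0) or np.any(np.asarray(reference_mz) <= 0):
        raise ValueError("m/z values must be positive")
    return (observed_mz - reference_mz) / reference_mz * 1e6


def find_internal_standard(pm: PeakMatrix, cfg: ISConfig) -> str:
    """Locate the internal-standard feature in an aligned matrix.

    Candidates are features whose representative m/z lies within
    ``cfg.ppm_tol`` of the expected adduct m/z; among them the one with the
    highest median intensity across non-blank samples wins (the IS is spiked
    at µM level and should dominate), ties broken by smallest |ppm error|.
    """
    if pm.n_features == 0:
        raise ValueError("empty peak matrix")
    err = ppm_error(pm.mz.to_numpy(), cfg.expected_mz)
    cand = pm.mz.index[np.abs(err) <= cfg.ppm_tol]
    if len(cand) == 0:
        raise ValueError(
            f"internal standard not detected: no feature within "
            f"±{cfg.ppm_tol} ppm of m/z {cfg.expected_mz}")
    non_blank = [s for s in pm.intensities.columns
                 if pm.samples.at[s, "class"] != "blank"]
    med = pm.intensities.loc[cand, non_blank].median(axis=1)
    abs_err = pd.Series(np.abs(ppm_error(pm.mz.loc[cand].to_numpy(),
                                         cfg.expected_mz)), index=cand)
    ranked = pd.DataFrame({"med": med, "abs_err": abs_err}).sort_values(
        ["med", "abs_err"], ascending=[False, True], kind="mergesort")
    return str(ranked.index[0])


def annotate_features(pm: PeakMatrix, compound_table: pd.DataFrame,
                      rules: list[AdductRule] | None = None,
                      ppm_tol: float = 5.0,
                      polarity: str = "positive") -> list[FeatureInfo]:
    """Putatively annotate every feature against a compound table.

    ``compound_table`` needs columns ``name`` and ``monoisotopic_mass``
    (neutral).  Every (feature, compound, adduct) triple within ``ppm_tol``
    is recorded; a feature may carry several annotations.  The result is
    independent of table row order and feature order.
    """
    rules = [r for r in (rules or ADDUCT_RULES) if r.polarity == polarity]
    infos = {fid: FeatureInfo(feature_id=str(fid), mz=float(m), polarity=polarity)
             for fid, m in pm.mz.items()}
    if compound_table is None or len(compound_table) == 0:
        import warnings
        warnings.warn("empty compound table: no annotations produced")
        return list(infos.values())
    mz = pm.mz.to_numpy()
    tab = compound_table.sort_values("name", kind="mergesort")
    for cname, mass in zip(tab["name"], tab["monoisotopic_mass"]):
        for rule in rules:
            target = mass + rule.mass_shift
            err = (mz - target) / target * 1e6
            for fid in pm.mz.index[np.abs(err) <= ppm_tol]:
                e = float(ppm_error(pm.mz.loc[fid], target))
                infos[fid].annotations.append((cname, rule.label, e))
    return list(infos.values())


def is_family_masses(is_mz: float, polarity: str = "positive",
                     rules: list[AdductRule] | None = None,
                     n_isotopes: int = 2) -> dict[str, float]:
    """m/z values derived from the internal standard: its other adducts and
    its first ``n_isotopes`` isotopologues (+1.00336 Da spacings)."""
    rules = [r for r in (rules or ADDUCT_RULES) if r.polarity == polarity]
    base_shift = PROTON if polarity == "positive" else -PROTON
    neutral = is_mz - base_shift
    fam = {}
    for r in rules:
        fam[r.label] = neutral + r.mass_shift
    for i in range(1, n_isotopes + 1):
        fam[f"M+{i} isotope"] = is_mz + C13_SPACING * i
    return fam


def strip_is_features(pm: PeakMatrix, is_feature: str, ppm_tol: float = 5.0,
                      polarity: str = "positive") -> tuple[PeakMatrix, pd.DataFrame]:
    """Remove the IS feature and its adduct/isotopologue partners.

    Returns the reduced matrix (for downstream statistics) and the removed
    rows' intensities, retained separately for QC reporting.  A feature is
    removed iff its m/z is within ``ppm_tol`` of the IS m/z, of any adduct
    of the IS's neutral mass, or of the IS +1/+2 isotopologue m/z.
    """
    is_mz = float(pm.mz.loc[is_feature])
    targets = list(is_family_masses(is_mz, polarity).values()) + [is_mz]
    mz = pm.mz.to_numpy()
    hit = np.zeros(len(mz), dtype=bool)
    for t in targets:
        hit |= np.abs((mz - t) / t * 1e6) <= ppm_tol
    removed = pm.mz.index[hit]
    kept = pm.mz.index[~hit]
    is_rows = pm.intensities.loc[removed].copy()
    return pm.subset(features=kept), is_rows
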