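"""Stage-specificity and epidermis-specificity screens.

Two screens are implemented:

* the four-region stage screen — per body region, a differential-expression
  gate (NB exact test, FDR < 0.01) comparing penultimate-instar nymphs with
  adults, plus three absolute TPM criteria:

  1. the minimum TPM of the high group is no less than 2 (>= 2),
  2. the maximum TPM of the low group is less than 2 (strict <),
  3. the minimum TPM of the high group is at least 1.5 times the maximum
     TPM of the low group (>= 1.5; strict > for the epidermis screen).

  A feature is nymph-specific (adult-specific) only if the gate and all
  three criteria hold with the nymph (adult) group high in every required
  region — the intersection across regions, with consistent direction.

* the epidermis screen (NES/AES) — untreated final-instar-nymph vs adult
  abdominal epidermis, DE gate plus the strict ratio criterion only (no
  absolute TPM floors; a deliberate difference between the two screens).

Min/max are taken over individual sample TPM values of a group, not group
means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .diffexpr import run_de
from .quantify import CountMatrix, compute_tpm

__all__ = [
    "ScreenConfig",
    "apply_tpm_criteria",
    "screen_stage_specific",
    "screen_epidermis_specific",
]

#: nymph region -> matching adult region; wing buds pair with adult wings,
#: caudal gills have no adult counterpart and stay out of the stage screen.
DEFAULT_REGION_PAIRS: tuple[tuple[str, str], ...] = (
    ("head", "head"),
    ("thorax", "thorax"),
    ("abdomen", "abdomen"),
    ("wing-buds", "wings"),
)


@dataclass
class ScreenConfig:
    """Thresholds for both screens (defaults are the published cut-offs)."""

    fdr_threshold: float = 0.01
    tpm_floor_high: float = 2.0  # criterion 1
    tpm_ceiling_low: float = 2.0  # criterion 2
    ratio_min: float = 1.5  # criterion 3
    ratio_strict: bool = False  # stage screen: ">= 1.5"; epidermis: "> 1.5"
    region_pairs: tuple[tuple[str, str], ...] = field(default=DEFAULT_REGION_PAIRS)

    def __post_init__(self) -> None:
        if min(self.fdr_threshold, self.tpm_floor_high, self.tpm_ceiling_low) <= 0:
            raise ValueError("thresholds must be > 0")
        if self.ratio_min <= 1:
            raise ValueError("ratio_min must be > 1")


def apply_tpm_criteria(
    tpm: pd.DataFrame,
    high_group,
    low_group,
    cfg: ScreenConfig | None = None,
    strict_ratio: bool | None = None,
) -> pd.DataFrame:
    """Per-feature boolean flags (c1, c2, c3) for one high/low comparison.

    c3 is true whenever max(low) = 0 and min(high) > 0 (infinite ratio).
    """
    cfg = cfg or ScreenConfig()
    strict = cfg.ratio_strict if strict_ratio is None else strict_ratio
    high_group, low_group = list(high_group), list(low_group)
    if not high_group or not low_group:
        raise ValueError("screen groups must be non-empty")
    if set(high_group) & set(low_group):
        raise ValueError("screen groups must be disjoint")
    mn_hi = tpm.loc[:, high_group].min(axis=1)
    mx_lo = tpm.loc[:, low_group].max(axis=1)
    c1 = mn_hi >= cfg.tpm_floor_high
    c2 = mx_lo < cfg.tpm_ceiling_low
    ratio_ok = (
        mn_hi > cfg.ratio_min * mx_lo if strict else mn_hi >= cfg.ratio_min * mx_lo
    )
    c3 = ((mx_lo > 0) & ratio_ok) | ((mx_lo == 0) & (mn_hi > 0))
    return pd.DataFrame({"c1": c1, "c2": c2, "c3": c3}, index=tpm.index)


def _region_groups(design: pd.DataFrame, cfg: ScreenConfig) -> dict[str, tuple[list, list]]:
    """Per region pair: (penultimate nymph sample ids, adult sample ids)."""
    dev = design[design["block"] == "development"]
    groups = {}
    for nymph_region, adult_region in cfg.region_pairs:
        nymph = dev[
            (dev["stage_class"] == "penultimate") & (dev["region"] == nymph_region)
        ]["sample_id"].tolist()
        adult = dev[(dev["stage_class"] == "adult") & (dev["region"] == adult_region)][
            "sample_id"
        ].tolist()
        if not nymph or not adult:
            raise ValueError(
                f"missing penultimate-nymph or adult samples for region pair "
                f"{nymph_region}/{adult_region}"
            )
        groups[nymph_region] = (nymph, adult)
    return groups


def stage_specificity_from_tpm(
    tpm: pd.DataFrame,
    region_groups: dict[str, tuple[list, list]],
    cfg: ScreenConfig | None = None,
    de_pass: dict[str, pd.Series] | None = None,
) -> pd.DataFrame:
    """Stage screen on precomputed TPM (optionally with per-region DE gates).

    Returns label plus flat per-region flag columns
    ``<region>_de, <region>_c1 .. <region>_c3, <region>_direction``.
    """
    cfg = cfg or ScreenConfig()
    out = pd.DataFrame(index=tpm.index)
    nymph_all = pd.Series(True, index=tpm.index)
    adult_all = pd.Series(True, index=tpm.index)
    for region, (nymph, adult) in region_groups.items():
        gate = (
            de_pass[region].reindex(tpm.index).fillna(False).astype(bool)
            if de_pass is not None
            else pd.Series(True, index=tpm.index)
        )
        as_nymph = apply_tpm_criteria(tpm, nymph, adult, cfg)
        as_adult = apply_tpm_criteria(tpm, adult, nymph, cfg)
        nymph_pass = gate & as_nymph.all(axis=1)
        adult_pass = gate & as_adult.all(axis=1)
        direction = pd.Series("none", index=tpm.index)
        direction[as_nymph.all(axis=1)] = "nymph"
        direction[as_adult.all(axis=1)] = "adult"
        out[f"{region}_de"] = gate
        for c in ("c1", "c2", "c3"):
            out[f"{region}_{c}"] = as_nymph[c] | as_adult[c]
        out[f"{region}_direction"] = direction
        nymph_all &= nymph_pass
        adult_all &= adult_pass
    label = pd.Series("none", index=tpm.index, name="label")
    label[nymph_all] = "nymph-specific"
    label[adult_all & ~nymph_all] = "adult-specific"
    out.insert(0, "label", label)
    out.index.name = "feature_id"
    return out


def screen_stage_specific(
    cm: CountMatrix,
    design: pd.DataFrame,
    cfg: ScreenConfig | None = None,
    de_gate: bool = True,
) -> pd.DataFrame:
    """Four-region stage-specificity screen on raw counts + sample design."""
    cfg = cfg or ScreenConfig()
    groups = _region_groups(design, cfg)
    tpm = compute_tpm(cm)
    de_pass = None
    if de_gate:
        de_pass = {}
        for region, (nymph, adult) in groups.items():
            de = run_de(cm, nymph, adult)
            de_pass[region] = de["fdr"] < cfg.fdr_threshold
    return stage_specificity_from_tpm(tpm, groups, cfg, de_pass)


def screen_epidermis_specific(
    cm: CountMatrix,
    design: pd.DataFrame,
    cfg: ScreenConfig | None = None,
    de_gate: bool = True,
) -> pd.DataFrame:
    """NES/AES screen on untreated abdominal-epidermis samples.

    DE gate (FDR < threshold) plus strict min(high)/max(low) > ratio_min;
    no absolute TPM floor/ceiling. Labels ``NES`` (nymph-high) and ``AES``
    (adult-high).
    """
    cfg = cfg or ScreenConfig()
    epi = design[(design["block"] == "epidermis") & (design["treatment"] == "untreated")]
    nymph = epi[epi["stage_class"] == "final"]["sample_id"].tolist()
    adult = epi[epi["stage_class"] == "adult"]["sample_id"].tolist()
    if not nymph or not adult:
        raise ValueError("untreated epidermis samples missing for nymph or adult group")
    tpm = compute_tpm(cm)
    as_nes = apply_tpm_criteria(tpm, nymph, adult, cfg, strict_ratio=True)["c3"]
    as_aes = apply_tpm_criteria(tpm, adult, nymph, cfg, strict_ratio=True)["c3"]
    if de_gate:
        de = run_de(cm, nymph, adult)
        gate = de["fdr"] < cfg.fdr_threshold
    else:
        gate = pd.Series(True, index=tpm.index)
    label = pd.Series("none", index=tpm.index, name="label")
    label[gate & as_nes] = "NES"
    label[gate & as_aes & ~as_nes] = "AES"
    out = pd.DataFrame(
        {"label": label, "de": gate, "ratio_nes": as_nes, "ratio_aes": as_aes}
    )
    out.index.name = "feature_id"
    return out
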