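"""RNAi-response classification and the {Kr-h1, broad, E93} Venn partition.

Electroporation-mediated RNAi is mosaic: an RNAi region contains affected
and unaffected cells, so measured knockdown is diluted and each RNAi region
is compared with the control region of the same individual. A feature
responds to a target when

1. the average expression over RNAi regions shows a more-than-1.5-fold
   change against the average over control regions (down means a ratio
   below 2/3), and
2. every individual shows the same tendency (all per-pair ratios on the
   same side of 1).

The affected subset of {Kr-h1, broad, E93} per feature defines the Venn
partition; its summary reports the per-region counts, the broad-involved
and non-broad totals, and the overall affected percentage. Paired t-tests
(RNAi vs control region) and Student's t-tests (untreated nymphs vs adults)
are reported as raw p-values; classification itself uses only the
fold/direction rules.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TARGETS",
    "VENN_REGIONS",
    "pair_samples",
    "classify_effect",
    "paired_t",
    "student_t",
    "venn_partition",
    "venn_summary",
]

TARGETS: tuple[str, ...] = ("Kr-h1", "broad", "E93")

#: canonical Venn region order: singletons, pairs, triple, unaffected
VENN_REGIONS: tuple[frozenset, ...] = (
    frozenset({"Kr-h1"}),
    frozenset({"broad"}),
    frozenset({"E93"}),
    frozenset({"Kr-h1", "broad"}),
    frozenset({"Kr-h1", "E93"}),
    frozenset({"broad", "E93"}),
    frozenset({"Kr-h1", "broad", "E93"}),
    frozenset(),
)


def region_key(subset: frozenset) -> str:
    """Stable string key for a Venn region, e.g. ``Kr-h1+broad`` or ``none``."""
    if not subset:
        return "none"
    return "+".join(t for t in TARGETS if t in subset)


def pair_samples(design: pd.DataFrame) -> pd.DataFrame:
    """RNAi/control sample pairs per (individual, target).

    Unpaired samples are excluded with a warning; two RNAi samples for one
    individual and target is an error.
    """
    rows = []
    rnai_block = design[design["treatment"].str.startswith(("rnai:", "control-region:"))]
    for (individual, target), grp in sorted(
        rnai_block.groupby(
            [rnai_block["individual"], rnai_block["treatment"].str.split(":").str[1]]
        ),
        key=lambda kv: kv[0],
    ):
        rnai = grp[grp["treatment"] == f"rnai:{target}"]["sample_id"].tolist()
        ctrl = grp[grp["treatment"] == f"control-region:{target}"]["sample_id"].tolist()
        if len(rnai) > 1 or len(ctrl) > 1:
            raise ValueError(
                f"individual {individual} has duplicate samples for target {target}"
            )
        if len(rnai) == 1 and len(ctrl) == 1:
            rows.append(
                {
                    "individual": individual,
                    "target": target,
                    "rnai_sample": rnai[0],
                    "control_sample": ctrl[0],
                }
            )
        else:
            warnings.warn(
                f"unpaired RNAi-block sample(s) for individual {individual}, "
                f"target {target}; excluded"
            )
    return pd.DataFrame(rows, columns=["individual", "target", "rnai_sample", "control_sample"])


def paired_t(values_rnai, values_control) -> tuple[float, float]:
    """Paired t-test (two-sided): one-sample t on differences vs 0, n-1 df."""
    x = np.asarray(values_rnai, dtype=float)
    y = np.asarray(values_control, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("paired_t needs two equal-length vectors of length >= 2")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        return math.inf * np.sign(d.mean()), 0.0  # zero variance, nonzero shift
    t, p = stats.ttest_rel(x, y)
    return float(t), float(p)


def student_t(group_a, group_b) -> tuple[float, float]:
    """Pooled-variance two-sample Student's t-test, two-sided."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("student_t needs >= 2 values per group")
    if np.allclose(a.std(ddof=1), 0.0) and np.allclose(b.std(ddof=1), 0.0):
        if np.allclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def classify_effect(
    tpm: pd.DataFrame,
    pairs: pd.DataFrame,
    fold_threshold: float = 1.5,
    down_threshold: float | None = None,
    mode: str = "ratio-of-means",
) -> pd.DataFrame:
    """Per feature x target: mean ratio, unanimity, direction, paired-t p.

    ``mean_ratio`` is the ratio of averages (mean RNAi TPM over pairs /
    mean control TPM) by default; ``mode="mean-of-ratios"`` averages the
    per-pair ratios instead. ``down_threshold`` defaults to
    1/``fold_threshold`` (the published "decreased to less than 2/3").
    Pairs whose two members are both zero are dropped from the unanimity
    check; a zero control mean with nonzero RNAi mean yields an infinite
    ratio flagged as direction up.
    """
    if down_threshold is None:
        down_threshold = 1.0 / fold_threshold
    records = []
    for target in sorted(pairs["target"].unique(), key=TARGETS.index):
        tp = pairs[pairs["target"] == target]
        if len(tp) < 2:
            raise ValueError(f"need >= 2 pairs for target {target}")
        r = tpm.loc[:, tp["rnai_sample"].tolist()].to_numpy()
        c = tpm.loc[:, tp["control_sample"].tolist()].to_numpy()
        mean_r, mean_c = r.mean(axis=1), c.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            if mode == "ratio-of-means":
                mean_ratio = mean_r / mean_c
            elif mode == "mean-of-ratios":
                mean_ratio = np.nanmean(np.where(c > 0, r / np.where(c > 0, c, 1), np.nan), axis=1)
            else:
                raise ValueError(f"unknown mode {mode!r}")
        mean_ratio = np.where((mean_c == 0) & (mean_r > 0), np.inf, mean_ratio)
        mean_ratio = np.where((mean_c == 0) & (mean_r == 0), np.nan, mean_ratio)
        informative = (r > 0) | (c > 0)  # both-zero pairs leave the unanimity check
        with np.errstate(divide="ignore", invalid="ignore"):
            above = np.where(informative, r > c, True).all(axis=1)
            below = np.where(informative, r < c, True).all(axis=1)
        any_informative = informative.any(axis=1)
        up = any_informative & (mean_ratio > fold_threshold) & above
        down = any_informative & (mean_ratio < down_threshold) & below
        direction = np.where(up, "up", np.where(down, "down", "none"))
        for i, feature in enumerate(tpm.index):
            tt, pp = paired_t(r[i], c[i])
            records.append(
                {
                    "feature_id": feature,
                    "target": target,
                    "mean_ratio": float(mean_ratio[i]),
                    "unanimous": bool(above[i] or below[i]) and bool(any_informative[i]),
                    "direction": str(direction[i]),
                    "paired_t_p": pp,
                }
            )
    return pd.DataFrame(records)


def venn_partition(
    effects: pd.DataFrame,
    features=None,
    expected_direction: Mapping[str, Mapping[str, str]] | None = None,
) -> pd.DataFrame:
    """Affected-subset per feature from per-target effect directions.

    Returns a DataFrame indexed by feature with one direction column per
    target, the affected ``subset`` (frozenset) and its string key. When
    ``expected_direction`` is given (e.g. NES: up under E93 RNAi, down under
    Kr-h1/broad RNAi), a ``consistent`` column annotates whether every
    non-none direction matches it; the subset itself is direction-agnostic.
    """
    present = set(effects["target"].unique())
    missing = set(TARGETS) - present
    if missing:
        raise ValueError(f"effects missing for target(s): {sorted(missing)}")
    wide = effects.pivot(index="feature_id", columns="target", values="direction")
    if features is not None:
        wide = wide.reindex(list(features))
    wide = wide.fillna("none")
    out = pd.DataFrame(index=wide.index)
    for t in TARGETS:
        out[f"direction_{t}"] = wide[t]
    subsets = wide.apply(
        lambda row: frozenset(t for t in TARGETS if row[t] != "none"), axis=1
    )
    out["subset"] = subsets
    out["subset_key"] = [region_key(s) for s in subsets]
    if expected_direction is not None:
        out["consistent"] = wide.apply(
            lambda row: all(
                row[t] == "none" or expected_direction.get(t) == row[t] for t in TARGETS
            ),
            axis=1,
        )
    return out


def venn_summary(partition: pd.DataFrame | Mapping[frozenset, int]) -> dict:
    """Region counts plus the derived totals of the Venn partition.

    Accepts either a partition DataFrame (from :func:`venn_partition`) or a
    direct mapping of region subsets to counts. ``broad_involved`` sums the
    four regions containing broad, ``non_broad_affected`` the three affected
    regions excluding broad, and ``affected_pct`` is
    100 * (set size - unaffected) / set size.
    """
    if isinstance(partition, pd.DataFrame):
        counts = {region: 0 for region in VENN_REGIONS}
        for subset in partition["subset"]:
            counts[frozenset(subset)] += 1
    else:
        counts = {region: int(partition.get(region, 0)) for region in VENN_REGIONS}
    total = sum(counts.values())
    unaffected = counts[frozenset()]
    broad_involved = sum(n for region, n in counts.items() if "broad" in region)
    non_broad_affected = sum(
        n for region, n in counts.items() if region and "broad" not in region
    )
    return {
        "region_counts": {region_key(region): counts[region] for region in VENN_REGIONS},
        "total": total,
        "unaffected": unaffected,
        "broad_involved": broad_involved,
        "non_broad_affected": non_broad_affected,
        "affected_pct": 100.0 * (total - unaffected) / total if total else 0.0,
    }
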