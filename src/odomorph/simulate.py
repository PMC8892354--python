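"""Synthetic damselfly transcriptome generator with planted ground truth.

Emulates the study design behind the screens: 82 untreated developmental
samples (13 whole-body stages from egg to seventh instar; penultimate and
final instar nymphs over head/thorax/abdomen/wing buds/caudal gills, nine
stages x five regions = 45; six adult individuals over four regions = 24),
untreated abdominal-epidermis replicates for the NES/AES screen, and paired
RNAi-region / control-region abdominal-epidermis samples for Kr-h1 (3
pairs), broad (4) and E93 (3).

Counts are negative-binomial (variance = mu + phi * mu^2) around
length-weighted expected fractions of a log-normal library size. Planted
features carry nymph-/adult-specific or epidermis-specific profiles and a
regulatory wiring (Kr-h1 -> broad, Kr-h1 -| E93, E93 -| broad by default)
whose RNAi responses are diluted by mosaic knockdown: a fraction m*e of the
cells in an RNAi region is affected, so a regulated feature's mean becomes
baseline * ((1 - m*e) + m*e * effect_fold^(+-1)).

Noise structure: samples from distinct individuals get independent
per-sample biological effects, while the two regions of one RNAi individual
share theirs — the within-individual pairing that motivates the paired
t-test — leaving only technical dispersion inside a pair. The marginal
dispersion of any single sample is still ``dispersion``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .quantify import CountMatrix
from .rnai import TARGETS, region_key

__all__ = [
    "DesignSpec",
    "GrnSpec",
    "gen_design",
    "gen_counts",
    "plant_screen_cases",
]

STAGES_WHOLE_BODY = (
    "egg_d2", "egg_d6", "egg_d10", "egg_d14", "egg_d18", "egg_d22",
    "instar1", "instar2", "instar3", "instar4", "instar5", "instar6", "instar7",
)
PENULTIMATE_STAGES = ("penult_early", "penult_mid", "penult_late")
FINAL_STAGES = ("final_1", "final_2a", "final_2b", "final_2c", "final_3a", "final_3b")
NYMPH_REGIONS = ("head", "thorax", "abdomen", "wing-buds", "caudal-gills")
ADULT_REGIONS = ("head", "thorax", "abdomen", "wings")
ADULT_INDIVIDUALS = (
    ("ad1", "male", "immature"),
    ("ad2", "male", "mature"),
    ("ad3", "female-gynochrome", "immature"),
    ("ad4", "female-gynochrome", "mature"),
    ("ad5", "female-androchrome", "immature"),
    ("ad6", "female-androchrome", "mature"),
)

DESIGN_COLUMNS = (
    "sample_id", "block", "stage", "stage_class", "region", "sex", "individual", "treatment",
)


@dataclass
class DesignSpec:
    """Sample layout; defaults reproduce the published 82-sample design.

    Replicate counts inside the 45/24 blocks are exposed as the stage and
    individual lists because the source design does not state them
    explicitly beyond the block totals.
    """

    stages_whole_body: tuple = STAGES_WHOLE_BODY
    penultimate_stages: tuple = PENULTIMATE_STAGES
    final_stages: tuple = FINAL_STAGES
    nymph_regions: tuple = NYMPH_REGIONS
    adult_regions: tuple = ADULT_REGIONS
    adult_individuals: tuple = ADULT_INDIVIDUALS
    n_rnai_pairs: dict = field(
        default_factory=lambda: {"Kr-h1": 3, "broad": 4, "E93": 3}
    )
    n_epidermis_nymph: int = 12
    n_epidermis_adult: int = 10
    library_size_mean: float = 1e7
    library_size_cv: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "stages_whole_body", "penultimate_stages", "final_stages",
            "nymph_regions", "adult_regions", "adult_individuals",
        ):
            if len(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be non-empty")
        if any(n < 1 for n in self.n_rnai_pairs.values()):
            raise ValueError("RNAi pair counts must be >= 1")
        if self.n_epidermis_nymph < 1 or self.n_epidermis_adult < 1:
            raise ValueError("epidermis replicate counts must be >= 1")
        if self.library_size_mean <= 0 or self.library_size_cv < 0:
            raise ValueError("library size parameters out of range")


def gen_design(spec: DesignSpec | None = None) -> pd.DataFrame:
    """One row per sample; deterministic given the spec.

    Blocks: ``development`` (the 82-sample block), ``epidermis`` (untreated
    abdominal-epidermis replicates for the NES/AES screen) and ``rnai``
    (paired rnai:<target> / control-region:<target> rows sharing an
    individual id).
    """
    spec = spec or DesignSpec()
    rows = []
    for i, stage in enumerate(spec.stages_whole_body):
        rows.append(
            dict(
                sample_id=f"wb_{stage}",
                block="development",
                stage=stage,
                stage_class="egg" if stage.startswith("egg") else "young-nymph",
                region="whole-body",
                sex="mixed",
                individual=f"wb{i + 1}",
                treatment="untreated",
            )
        )
    for stage_class, stages in (
        ("penultimate", spec.penultimate_stages),
        ("final", spec.final_stages),
    ):
        for stage in stages:
            for region in spec.nymph_regions:
                rows.append(
                    dict(
                        sample_id=f"ny_{stage}_{region}",
                        block="development",
                        stage=stage,
                        stage_class=stage_class,
                        region=region,
                        sex="mixed",
                        individual=f"ny_{stage}",
                        treatment="untreated",
                    )
                )
    for ind, sex, maturity in spec.adult_individuals:
        for region in spec.adult_regions:
            rows.append(
                dict(
                    sample_id=f"ad_{ind}_{region}",
                    block="development",
                    stage=f"adult-{maturity}",
                    stage_class="adult",
                    region=region,
                    sex=sex,
                    individual=ind,
                    treatment="untreated",
                )
            )
    for i in range(spec.n_epidermis_nymph):
        rows.append(
            dict(
                sample_id=f"epi_nymph{i + 1}",
                block="epidermis",
                stage="final_1",
                stage_class="final",
                region="abdomen",
                sex="mixed",
                individual=f"epn{i + 1}",
                treatment="untreated",
            )
        )
    for i in range(spec.n_epidermis_adult):
        rows.append(
            dict(
                sample_id=f"epi_adult{i + 1}",
                block="epidermis",
                stage="adult-immature",
                stage_class="adult",
                region="abdomen",
                sex="mixed",
                individual=f"epa{i + 1}",
                treatment="untreated",
            )
        )
    for target in TARGETS:
        for i in range(spec.n_rnai_pairs.get(target, 0)):
            individual = f"{target}_ind{i + 1}"
            for treatment in (f"rnai:{target}", f"control-region:{target}"):
                kind = treatment.split(":")[0].replace("-region", "")
                rows.append(
                    dict(
                        sample_id=f"{kind}_{target}_{i + 1}",
                        block="rnai",
                        stage="final_late",
                        stage_class="final",
                        region="abdomen",
                        sex="mixed",
                        individual=individual,
                        treatment=treatment,
                    )
                )
    design = pd.DataFrame(rows, columns=list(DESIGN_COLUMNS))
    if design["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in generated design")
    return design


@dataclass
class GrnSpec:
    """Regulatory wiring and mosaic knockdown parameters.

    ``edges`` are (regulator, target feature, sign) with sign ``+`` for
    activation (target drops under the regulator's RNAi) and ``-`` for
    repression (target rises). The defaults encode Kr-h1 -> broad,
    Kr-h1 -| E93 and E93 -| broad. Each RNAi'd regulator is also knocked
    down itself (residual expression 1 - knockdown_efficiency in affected
    cells).
    """

    edges: tuple = (
        ("Kr-h1", "broad", "+"),
        ("Kr-h1", "E93", "-"),
        ("E93", "broad", "-"),
    )
    effect_fold: float = 10.0
    knockdown_efficiency: float = 0.95
    mosaic_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.knockdown_efficiency <= 1.0:
            raise ValueError("knockdown_efficiency must be in [0, 1]")
        if not 0.0 <= self.mosaic_fraction <= 1.0:
            raise ValueError("mosaic_fraction must be in [0, 1]")
        if self.effect_fold < 1.0:
            raise ValueError("effect_fold must be >= 1 (use sign for direction)")
        for reg, _target, sign in self.edges:
            if reg not in TARGETS or sign not in "+-":
                raise ValueError(f"bad edge ({reg}, _, {sign})")

    def multiplier(self, sign: str) -> float:
        """Mean multiplier in an RNAi region for a regulated feature.

        Cell mixture: a fraction m*e of cells is affected; in those the
        target is scaled by effect_fold (repressed target, sign ``-``) or
        1/effect_fold (activated target, sign ``+``).
        """
        me = self.mosaic_fraction * self.knockdown_efficiency
        fold = self.effect_fold if sign == "-" else 1.0 / self.effect_fold
        mult = (1.0 - me) + me * fold
        if mult < 0:
            raise ValueError("infeasible plant: negative mean")
        return mult

    def self_multiplier(self) -> float:
        me = self.mosaic_fraction * self.knockdown_efficiency
        return (1.0 - me) + me * (1.0 - self.knockdown_efficiency)


# Planted nominal TPM levels per sample context:
# (dev-nymph, dev-adult, epi-nymph, epi-adult, rnai-baseline)
_LEVELS = {
    "nymph-specific": (10.0, 0.4, 2.0, 2.0, 2.0),
    "adult-specific": (0.4, 10.0, 2.0, 2.0, 2.0),
    "NES": (2.0, 2.0, 10.0, 0.4, 10.0),
    # the adult program rises late in the final instar, so AES plants keep a
    # solid RNAi-block baseline: fold changes stay measurable at count level
    "AES": (2.0, 2.0, 2.0, 20.0, 10.0),
    "Kr-h1": (10.0, 0.4, 0.4, 0.4, 0.4),  # very low in final instar
    "broad": (10.0, 0.4, 10.0, 0.4, 10.0),
    "E93": (0.4, 10.0, 0.4, 10.0, 10.0),
    "fail-c1": (1.2, 0.05, 2.0, 2.0, 2.0),
    "fail-c2": (20.0, 3.0, 2.0, 2.0, 2.0),
    "fail-c3": (3.0, 2.4, 2.0, 2.0, 2.0),
}

#: Venn subsets planted on the generic NES/AES features, one feature each.
_PLANT_SUBSETS = (
    (),
    ("Kr-h1",),
    ("broad",),
    ("E93",),
    ("Kr-h1", "broad"),
    ("Kr-h1", "E93"),
    ("broad", "E93"),
    ("Kr-h1", "broad", "E93"),
)


def _subset_slug(subset) -> str:
    if not subset:
        return "none"
    return "_".join(t.replace("-", "").lower() for t in TARGETS if t in subset)


def _planted_features(grn: GrnSpec):
    """Feature plan: (id, class, nes/aes role, venn subset, failure tag, edges)."""
    plan = []
    plan.append(("Kr-h1", "nymph-specific", "none", frozenset(), "", ()))
    plan.append(
        ("broad", "nymph-specific", "NES", frozenset({"Kr-h1", "broad", "E93"}), "",
         (("Kr-h1", "+"), ("E93", "-")))
    )
    plan.append(
        ("E93", "adult-specific", "AES", frozenset({"Kr-h1", "E93"}), "",
         (("Kr-h1", "-"),))
    )
    for i in range(6):
        plan.append((f"N{i + 1:02d}", "nymph-specific", "none", frozenset(), "", ()))
    for i in range(6):
        plan.append((f"A{i + 1:02d}", "adult-specific", "none", frozenset(), "", ()))
    for role, expected in (("NES", {"Kr-h1": "+", "broad": "+", "E93": "-"}),
                           ("AES", {"Kr-h1": "-", "broad": "-", "E93": "+"})):
        for subset in _PLANT_SUBSETS:
            edges = tuple((t, expected[t]) for t in subset)
            plan.append(
                (f"{role}_{_subset_slug(subset)}", role, role, frozenset(subset), "", edges)
            )
    for tag in ("c1", "c2", "c3"):
        plan.append((f"FAIL_{tag.upper()}", "background", "none", frozenset(), tag, ()))
    return plan


def _context_index(design: pd.DataFrame) -> np.ndarray:
    """Column index into the 5-level pattern tuples, per sample."""
    ctx = np.empty(len(design), dtype=int)
    for i, row in enumerate(design.itertuples(index=False)):
        if row.block == "rnai":
            ctx[i] = 4
        elif row.block == "epidermis":
            ctx[i] = 3 if row.stage_class == "adult" else 2
        else:
            ctx[i] = 1 if row.stage_class == "adult" else 0
    return ctx


def gen_counts(
    design: pd.DataFrame,
    grn: GrnSpec | None = None,
    n_features: int = 2000,
    seed: int = 0,
    dispersion: float = 0.05,
    technical_dispersion: float = 0.005,
    library_size_mean: float = 1e7,
    library_size_cv: float = 0.25,
    female_abdomen_krh1_fold: float = 1.0,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Seeded NB count matrix plus the planted TruthTable.

    ``dispersion`` is the marginal NB dispersion of any single sample
    (variance = mu + phi*mu^2). Within an RNAi individual the rnai and
    control samples share the biological component, leaving
    ``technical_dispersion`` inside the pair. ``female_abdomen_krh1_fold``
    optionally elevates Kr-h1 in adult female abdomens (off at 1.0).
    """
    grn = grn or GrnSpec()
    plan = _planted_features(grn)
    if n_features < len(plan):
        raise ValueError(f"n_features must be >= {len(plan)} (planted features)")
    if dispersion < 0 or technical_dispersion < 0:
        raise ValueError("dispersions must be >= 0")
    rng = np.random.default_rng(seed)
    n_bg = n_features - len(plan)
    feature_ids = [p[0] for p in plan] + [f"BG{i + 1:04d}" for i in range(n_bg)]
    samples = design["sample_id"].tolist()

    # nominal TPM level matrix
    ctx = _context_index(design)
    levels = np.empty((n_features, len(samples)))
    for k, (fid, klass, role, _subset, tag, _edges) in enumerate(plan):
        key = fid if fid in _LEVELS else (f"fail-{tag}" if tag else klass)
        if key not in _LEVELS:
            key = role
        levels[k] = np.asarray(_LEVELS[key])[ctx]
    bg = rng.lognormal(mean=0.0, sigma=1.0, size=n_bg)
    bg *= (1e6 - levels[: len(plan)].mean(axis=1).sum()) / bg.sum()
    levels[len(plan):] = bg[:, None]

    if female_abdomen_krh1_fold != 1.0:
        mask = (
            (design["stage_class"] == "adult")
            & (design["region"] == "abdomen")
            & design["sex"].str.startswith("female")
        ).to_numpy()
        levels[feature_ids.index("Kr-h1"), mask] *= female_abdomen_krh1_fold

    # RNAi effects: regulated features and the target's own knockdown
    edge_mult = {}  # (feature_row, target) -> multiplier
    for k, (fid, _klass, _role, _subset, _tag, edges) in enumerate(plan):
        for target, sign in edges:
            edge_mult[(k, target)] = grn.multiplier(sign)
        if fid in TARGETS:
            edge_mult[(k, fid)] = grn.self_multiplier()
    for j, row in enumerate(design.itertuples(index=False)):
        if row.treatment.startswith("rnai:"):
            target = row.treatment.split(":", 1)[1]
            for (k, tgt), mult in edge_mult.items():
                if tgt == target:
                    levels[k, j] *= mult

    lengths = np.concatenate(
        [np.full(len(plan), 2500.0), rng.integers(500, 5001, size=n_bg).astype(float)]
    )
    weighted = levels * lengths[:, None]
    fractions = weighted / weighted.sum(axis=0, keepdims=True)

    sigma_lib = np.sqrt(np.log1p(library_size_cv**2))
    libs = rng.lognormal(np.log(library_size_mean) - sigma_lib**2 / 2, sigma_lib,
                         size=len(samples))
    mu = fractions * libs[None, :]

    # Untreated samples come from distinct individuals: plain NB(mu, phi).
    # Within the RNAi block the two regions of one individual share a
    # biological lognormal effect; only technical dispersion remains inside
    # the pair, while the marginal dispersion of each sample stays ~phi.
    phi_tech = min(technical_dispersion, dispersion)
    bio_var = max((dispersion - phi_tech) / (1.0 + phi_tech), 0.0)
    sigma_bio = np.sqrt(np.log1p(bio_var))
    bio = np.ones_like(mu)
    individuals = design["individual"].tolist()
    in_rnai = (design["block"] == "rnai").tolist()
    first_col: dict[str, int] = {}
    for j, ind in enumerate(individuals):
        if not in_rnai[j]:
            continue
        if ind in first_col:
            bio[:, j] = bio[:, first_col[ind]]  # paired regions share biology
        else:
            bio[:, j] = rng.lognormal(-sigma_bio**2 / 2, sigma_bio, size=mu.shape[0])
            first_col[ind] = j
    mean = mu * bio
    phi_col = np.where(np.asarray(in_rnai), phi_tech, dispersion)
    counts = np.empty(mu.shape, dtype=np.int64)
    for j in range(mu.shape[1]):
        if phi_col[j] == 0:
            counts[:, j] = rng.poisson(mean[:, j])
        else:
            r = 1.0 / phi_col[j]
            counts[:, j] = rng.negative_binomial(r, r / (r + mean[:, j]))

    cm = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(feature_ids, name="feature_id"),
                     columns=samples),
        pd.Series(lengths, index=feature_ids, name="length"),
    )
    truth = pd.DataFrame(
        [
            {
                "feature_id": fid,
                "klass": klass,
                "nes_aes": role,
                "venn": region_key(subset),
                "failure_mode": tag,
            }
            for fid, klass, role, subset, tag, _ in plan
        ]
        + [
            {"feature_id": f, "klass": "background", "nes_aes": "none",
             "venn": "none", "failure_mode": ""}
            for f in feature_ids[len(plan):]
        ]
    ).set_index("feature_id")
    return cm, truth


def plant_screen_cases() -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Deterministic noise-free TPM fixture exercising every screen rule.

    Returns (tpm, truth, region_groups): two nymph and two adult samples per
    region pair, identical values in all four regions; the truth table
    carries the expected criteria flags (non-strict ratio), the expected
    strict-ratio outcome, the stage label and the violated-criterion tag.
    """
    cases = {
        # id: (nymph values, adult values, c1, c2, c3, c3_strict, label, tag)
        "ok_nymph": ((5, 6), (0.1, 0.2), True, True, True, True, "nymph-specific", ""),
        "ok_adult": ((0.1, 0.2), (5, 6), True, True, True, True, "adult-specific", ""),
        "fail_c1": ((1.9, 10), (0.0, 0.0), False, True, True, True, "none", "c1"),
        "fail_c2": ((5, 6), (2.1, 0.5), True, False, True, True, "none", "c2"),
        "fail_c3": ((2.5, 3), (1.9, 1.0), True, True, False, False, "none", "c3"),
        "floor_boundary": ((2.0, 6), (0.5, 0.25), True, True, True, True,
                           "nymph-specific", ""),
        "ceiling_boundary": ((5, 6), (2.0, 0.1), True, False, True, True, "none", "c2"),
        "ratio_boundary": ((1.5, 8), (1.0, 0.5), False, True, True, False, "none", "c1"),
    }
    regions = [nymph for nymph, _adult in
               (("head", "head"), ("thorax", "thorax"),
                ("abdomen", "abdomen"), ("wing-buds", "wings"))]
    columns, region_groups = [], {}
    for region in regions:
        nymph_cols = [f"{region}_pen{i}" for i in (1, 2)]
        adult_cols = [f"{region}_ad{i}" for i in (1, 2)]
        region_groups[region] = (nymph_cols, adult_cols)
        columns += nymph_cols + adult_cols
    data = {}
    for fid, (ny, ad, *_rest) in cases.items():
        row = []
        for _region in regions:
            row += list(ny) + list(ad)
        data[fid] = row
    tpm = pd.DataFrame.from_dict(data, orient="index", columns=columns).astype(float)
    tpm.index.name = "feature_id"
    truth = pd.DataFrame(
        [
            {"feature_id": fid, "c1": c1, "c2": c2, "c3": c3, "c3_strict": c3s,
             "label": label, "failure_mode": tag}
            for fid, (_ny, _ad, c1, c2, c3, c3s, label, tag) in cases.items()
        ]
    ).set_index("feature_id")
    return tpm, truth, region_groups


def design_spec_fields() -> tuple[str, ...]:
    return tuple(f.name for f in fields(DesignSpec))
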