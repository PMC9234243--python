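"""Synthetic multi-tissue cold-exposure lipidomics studies with ground truth.

The generator emulates the study design the pipeline is built for: two
housing temperatures (cold, room) with 6 mice per group, plasma plus nine
solid tissues, class-structured lipid panels quantified against per-class
internal standards, log-normal measurement noise, and planted effects:

* per-lipid log2 temperature shifts (cold-responsive lipids);
* contributor / consumer relationships between tissue lipids and chosen
  plasma lipids, planted on the standardized log scale as a partial
  correlation of ``beta2`` given temperature (positive = contribution,
  negative = uptake/consumption).  Each planted link loads on a latent
  per-target factor with weight sqrt(|beta2|), so every link attains the
  designed partial correlation regardless of how many links a plasma
  target has.

Raw peak areas are emitted such that internal-standard normalization
recovers the planted pmol values exactly; all randomness is keyed off the
design seed through independent substreams, so adding lipids or tissues
never perturbs existing draws and identical seeds give identical tables.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .curation import FeatureAnnotation
from .nomenclature import canonical_key, lipid_class_of, parse_lipid_name
from .quantify import AbundanceTable, InternalStandardMap, is_normalize

__all__ = [
    "StudyDesign",
    "GroundTruth",
    "SyntheticStudy",
    "AnnotationFixture",
    "generate_study",
    "generate_annotation_fixture",
    "evaluate_recovery",
    "RecoveryMetrics",
    "small_design",
]

DEFAULT_TISSUES = (
    "plasma", "liver", "BAT", "iWAT", "eWAT",
    "kidney", "intestine", "lung", "heart", "GSM",
)

# Panel sizes follow the magnitudes seen in deep multi-tissue profiling
# (plasma the smallest panel, kidney the largest).
DEFAULT_PANEL_SIZES: dict[str, int] = {
    "plasma": 457, "liver": 638, "BAT": 600, "iWAT": 550, "eWAT": 550,
    "kidney": 855, "intestine": 800, "lung": 780, "heart": 500, "GSM": 434,
}

# Species the analyses address by name: the major acylcarnitines and
# ceramides are always present in the plasma panel, and the major
# acylcarnitines also in liver and BAT (the plasma-liver-BAT axis).
PLASMA_FOCUS_LIPIDS = (
    "ACar 16:0", "ACar 18:0", "ACar 18:1",
    "Cer_NS d18:1_22:0", "Cer_NS d18:1_24:0", "Cer_NS d18:1_24:1",
)
_ACAR_FOCUS = ("ACar 16:0", "ACar 18:0", "ACar 18:1")
FOCUS_LIPIDS: dict[str, tuple[str, ...]] = {
    "plasma": PLASMA_FOCUS_LIPIDS,
    "liver": _ACAR_FOCUS,
    "BAT": _ACAR_FOCUS,
}

_CLASS_WEIGHTS = {
    "PC": 0.18, "PE": 0.12, "TG": 0.12, "DG": 0.04, "FA": 0.07,
    "ACar": 0.04, "Cer": 0.08, "SM": 0.06, "LPC": 0.05, "LPE": 0.04,
    "PI": 0.05, "PS": 0.04, "PG": 0.03, "CL": 0.03, "HexCer": 0.05,
}

# pmol spiked per class; the acylcarnitine standard is the 300 pmol
# deuterated oleoyl-carnitine, the rest are SPLASH-style class standards.
DEFAULT_SPIKED_PMOL = {cls: (300.0 if cls == "ACar" else 100.0) for cls in _CLASS_WEIGHTS}
DEFAULT_IS_IDENTITIES = {
    cls: ("oleoyl-carnitine-d3" if cls == "ACar" else f"SPLASH {cls} standard")
    for cls in _CLASS_WEIGHTS
}


@dataclass(frozen=True)
class StudyDesign:
    """Parameters of one synthetic study.

    Effects are on the log2 scale; ``link_beta2`` is the planted partial
    correlation (given temperature) between each linked tissue lipid and
    its plasma target on the standardized scale.
    """

    tissues: tuple[str, ...] = DEFAULT_TISSUES
    n_per_group: int = 6
    panel_sizes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_PANEL_SIZES))
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 2.0
    noise_sd: float = 0.5
    frac_temperature_responsive: float = 0.10
    temperature_shift_log2: float = 1.0
    target_lipids: tuple[str, ...] = ("ACar 18:1", "Cer_NS d18:1_22:0")
    target_shift_log2: float = 2.0
    contributor_tissue: str = "liver"
    consumer_tissue: str = "BAT"
    links_per_target: int = 4
    link_beta2: float = 0.8
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        if not -1 < self.link_beta2 < 1:
            raise ValueError("link_beta2 must be a partial correlation in (-1, 1)")
        if not 0 <= self.missing_rate < 0.5:
            raise ValueError("missing_rate must be in [0, 0.5)")
        missing = [t for t in self.tissues if t not in self.panel_sizes]
        if missing:
            raise ValueError(f"panel_sizes missing tissues: {missing}")
        if self.links_per_target:
            for t in (self.contributor_tissue, self.consumer_tissue):
                if t not in self.tissues:
                    raise ValueError(f"linked tissue {t!r} not in design tissues")
        if "plasma" not in self.tissues:
            raise ValueError("design must include plasma")


def small_design(**overrides) -> StudyDesign:
    """A scaled-down design for fast exercises: tens of lipids per tissue."""
    defaults = dict(
        tissues=("plasma", "liver", "BAT", "kidney"),
        panel_sizes={"plasma": 40, "liver": 50, "BAT": 45, "kidney": 40},
        links_per_target=4,
    )
    defaults.update(overrides)
    return StudyDesign(**defaults)


@dataclass
class GroundTruth:
    """What was planted, keyed the way the pipeline reports results."""

    temperature_shifts: dict[str, dict[str, float]]  # tissue -> lipid key -> log2 shift
    links: pd.DataFrame  # tissue, tissue_lipid, plasma_lipid, beta2
    targets: tuple[str, ...]
    contributor_tissue: str
    consumer_tissue: str
    seed: int


@dataclass
class TissueRaw:
    """Raw emission for one tissue: peak areas, IS areas+amounts, metadata."""

    areas: pd.DataFrame  # lipid key x sample, raw peak areas (NaN = not detected)
    is_map: InternalStandardMap
    meta: pd.DataFrame


@dataclass
class SyntheticStudy:
    design: StudyDesign
    truth: GroundTruth
    raw: dict[str, TissueRaw]

    def normalized(self, tissue: str) -> AbundanceTable:
        r = self.raw[tissue]
        return is_normalize(r.areas, r.is_map, r.meta)

    def normalized_all(self) -> dict[str, AbundanceTable]:
        return {t: self.normalized(t) for t in self.raw}


# --------------------------------------------------------------------------
# lipid panel generation

_ACYL_CARBONS = np.array([12, 14, 15, 16, 17, 18, 20, 22, 24])
_ACYL_WEIGHTS = np.array([2, 5, 1, 12, 2, 14, 6, 4, 2], dtype=float)
_CER_ACYLS = np.array([16, 18, 20, 22, 23, 24, 26])
_SPHINGOID = ["d18:1", "d18:0", "d18:2"]


def _random_acyl(rng: np.random.Generator) -> str:
    c = int(rng.choice(_ACYL_CARBONS, p=_ACYL_WEIGHTS / _ACYL_WEIGHTS.sum()))
    d = int(rng.integers(0, min(6, c // 3) + 1))
    return f"{c}:{d}"


def _random_name(cls: str, rng: np.random.Generator) -> str:
    if cls == "ACar":
        c = int(rng.choice([12, 14, 16, 18, 20]))
        return f"ACar {c}:{int(rng.integers(0, 3))}"
    if cls == "FA":
        return f"FA {_random_acyl(rng)}"
    if cls in ("LPC", "LPE"):
        return f"{cls} {_random_acyl(rng)}"
    if cls == "Cer":
        base = rng.choice(_SPHINGOID, p=[0.7, 0.2, 0.1])
        acyl = int(rng.choice(_CER_ACYLS))
        return f"Cer_NS {base}_{acyl}:{int(rng.integers(0, 2))}"
    if cls == "HexCer":
        base = rng.choice(_SPHINGOID, p=[0.8, 0.1, 0.1])
        acyl = int(rng.choice(_CER_ACYLS))
        return f"HexCer {base}_{acyl}:{int(rng.integers(0, 2))}"
    if cls == "SM":
        base = rng.choice(_SPHINGOID, p=[0.8, 0.1, 0.1])
        acyl = int(rng.choice(_CER_ACYLS))
        return f"SM {base}_{acyl}:{int(rng.integers(0, 2))}"
    if cls == "TG":
        if rng.random() < 0.3:  # sum composition
            c = int(rng.integers(44, 58))
            return f"TG {c}:{int(rng.integers(0, 9))}"
        return "TG " + "_".join(_random_acyl(rng) for _ in range(3))
    if cls == "CL":
        return "CL " + "_".join(_random_acyl(rng) for _ in range(4))
    # diacyl glycerophospholipids / DG
    if rng.random() < 0.25:  # sum composition
        c = int(rng.integers(30, 42))
        return f"{cls} {c}:{int(rng.integers(0, 9))}"
    return f"{cls} " + "_".join(_random_acyl(rng) for _ in range(2))


def _generate_panel(tissue: str, size: int, rng: np.random.Generator) -> list[str]:
    """Unique canonical keys for one tissue's lipid panel."""
    classes = list(_CLASS_WEIGHTS)
    probs = np.array([_CLASS_WEIGHTS[c] for c in classes])
    probs /= probs.sum()
    keys: list[str] = []
    seen: set[str] = set()
    for raw in FOCUS_LIPIDS.get(tissue, ()):
        key = canonical_key(parse_lipid_name(raw))
        seen.add(key)
        keys.append(key)
    guard = 0
    while len(keys) < size:
        guard += 1
        if guard > 100 * size + 1000:
            raise RuntimeError(f"could not build a unique panel of {size} for {tissue}")
        cls = classes[int(rng.choice(len(classes), p=probs))]
        key = canonical_key(parse_lipid_name(_random_name(cls, rng)))
        if key not in seen:
            seen.add(key)
            keys.append(key)
    return keys[:size]


# --------------------------------------------------------------------------
# study generation


def _mouse_ids(design: StudyDesign) -> tuple[list[str], np.ndarray]:
    n = 2 * design.n_per_group
    mice = [f"m{i + 1:02d}" for i in range(n)]
    cold = np.zeros(n, dtype=bool)
    cold[: design.n_per_group] = True
    return mice, cold


def generate_study(design: StudyDesign) -> SyntheticStudy:
    """Emit raw per-tissue tables plus the ground truth of what was planted."""
    mice, cold = _mouse_ids(design)
    n = len(mice)
    t_index = {t: i for i, t in enumerate(design.tissues)}

    panels = {
        t: _generate_panel(t, design.panel_sizes[t], np.random.default_rng([design.seed, 1, t_index[t]]))
        for t in design.tissues
    }
    for target in design.target_lipids:
        tkey = canonical_key(parse_lipid_name(target))
        if tkey not in panels["plasma"]:
            raise ValueError(f"target {target!r} not in plasma panel")

    # latent per-target factors shared by the plasma target and its links
    factors = {
        k: np.random.default_rng([design.seed, 3, k]).normal(size=n)
        for k in range(len(design.target_lipids))
    }
    b = abs(design.link_beta2)
    load = np.sqrt(b)
    resid = np.sqrt(1.0 - b)

    # linked tissue lipids: (tissue, lipid key) -> (target index, sign)
    link_rows = []
    link_of: dict[tuple[str, str], tuple[int, float]] = {}
    if design.links_per_target:
        for k, target in enumerate(design.target_lipids):
            tkey = canonical_key(parse_lipid_name(target))
            for tissue, sign in ((design.contributor_tissue, 1.0), (design.consumer_tissue, -1.0)):
                panel = [key for key in panels[tissue]]
                lo = k * design.links_per_target
                hi = lo + design.links_per_target
                if hi > len(panel):
                    raise ValueError(f"{tissue} panel too small for the requested links")
                for key in panel[lo:hi]:
                    link_of[(tissue, key)] = (k, sign)
                    link_rows.append(
                        {"tissue": tissue, "tissue_lipid": key,
                         "plasma_lipid": tkey, "beta2": sign * b}
                    )
    links = pd.DataFrame(link_rows, columns=["tissue", "tissue_lipid", "plasma_lipid", "beta2"])

    target_keys = {
        canonical_key(parse_lipid_name(t)): k for k, t in enumerate(design.target_lipids)
    }

    shifts: dict[str, dict[str, float]] = {}
    raw: dict[str, TissueRaw] = {}
    for tissue in design.tissues:
        ti = t_index[tissue]
        sample_ids = [f"{tissue}_{m}" for m in mice]
        rng_amount = np.random.default_rng([design.seed, 4, ti])
        if tissue == "plasma":
            amounts = rng_amount.uniform(0.018, 0.022, size=n)  # ml
        else:
            amounts = rng_amount.uniform(15.0, 25.0, size=n)  # mg

        classes = sorted({lipid_class_of(k) for k in panels[tissue]})
        # one substream per class so a class added later never shifts
        # the IS draws of classes already present
        is_areas = pd.DataFrame(
            np.vstack(
                [
                    np.random.default_rng(
                        [design.seed, 5, ti, zlib.crc32(cls.encode())]
                    ).lognormal(mean=np.log(1e5), sigma=0.2, size=n)
                    for cls in classes
                ]
            ),
            index=classes,
            columns=sample_ids,
        )
        meta = pd.DataFrame(
            {
                "mouse_id": mice,
                "tissue": tissue,
                "temperature": np.where(cold, "cold", "room"),
                "amount": amounts,
            },
            index=sample_ids,
        )

        tissue_shifts: dict[str, float] = {}
        values = np.empty((len(panels[tissue]), n))
        for j, key in enumerate(panels[tissue]):
            rng = np.random.default_rng([design.seed, 2, ti, j])
            base = rng.normal(design.baseline_log2_mean, design.baseline_log2_sd)
            responsive = rng.random() < design.frac_temperature_responsive
            sign_up = rng.random() < 0.5
            eps = rng.normal(size=n)
            missing = rng.random(size=n) < design.missing_rate

            if tissue == "plasma" and key in target_keys:
                k = target_keys[key]
                shift = design.target_shift_log2
                z = load * factors[k] + resid * eps
            elif (tissue, key) in link_of:
                k, sign = link_of[(tissue, key)]
                shift = design.temperature_shift_log2
                z = sign * load * factors[k] + resid * eps
            else:
                shift = (
                    (design.temperature_shift_log2 if sign_up else -design.temperature_shift_log2)
                    if responsive else 0.0
                )
                z = eps
            if shift != 0.0:
                tissue_shifts[key] = shift
            log2_val = base + shift * cold.astype(float) + design.noise_sd * z
            row = np.exp2(log2_val)
            row[missing] = np.nan
            values[j] = row

        pmol = pd.DataFrame(values, index=panels[tissue], columns=sample_ids)
        spiked = {c: DEFAULT_SPIKED_PMOL[c] for c in classes}
        is_map = InternalStandardMap(
            spiked_pmol=spiked,
            areas=is_areas,
            identities={c: DEFAULT_IS_IDENTITIES[c] for c in classes},
        )
        # invert the normalization so is_normalize recovers pmol exactly
        denom = is_areas.loc[[lipid_class_of(k) for k in panels[tissue]]].set_axis(pmol.index)
        pmol_per_is = pd.Series(spiked).loc[[lipid_class_of(k) for k in panels[tissue]]].set_axis(pmol.index)
        areas = pmol.mul(pd.Series(amounts, index=sample_ids), axis=1).mul(denom).div(pmol_per_is, axis=0)
        shifts[tissue] = tissue_shifts
        raw[tissue] = TissueRaw(areas=areas, is_map=is_map, meta=meta)

    truth = GroundTruth(
        temperature_shifts=shifts,
        links=links,
        targets=tuple(canonical_key(parse_lipid_name(t)) for t in design.target_lipids),
        contributor_tissue=design.contributor_tissue,
        consumer_tissue=design.consumer_tissue,
        seed=design.seed,
    )
    return SyntheticStudy(design=design, truth=truth, raw=raw)


# --------------------------------------------------------------------------
# annotation fixtures


@dataclass
class AnnotationFixture:
    positive: list[FeatureAnnotation]
    negative: list[FeatureAnnotation]
    survivors: list[FeatureAnnotation]  # intended curated output


def generate_annotation_fixture(
    n_lipids: int = 20,
    scheme: Mapping[str, int] | None = None,
    seed: int = 0,
) -> AnnotationFixture:
    """Raw dual-mode annotation lists with planted, forced redundancies.

    ``scheme`` gives counts of planted duplicate groups:
    ``rt_twin`` (same identity re-integrated within the retention-time
    tolerance, abundance kept above the intensity cutoff so only the RT
    rule fires), ``satellite`` (a far-eluting adduct/fragment below 25%
    of the dominant annotation), ``dual_mode`` (the identity annotated in
    both ionizations with one mode weaker).  Remaining lipids are unique.
    The intended curated survivors are returned alongside and are forced
    by construction.
    """
    scheme = dict(scheme or {"rt_twin": 3, "satellite": 3, "dual_mode": 3})
    n_dup = sum(scheme.values())
    if n_dup > n_lipids:
        raise ValueError("more duplicate groups than lipids")
    rng = np.random.default_rng([seed, 7])
    keys: list[str] = []
    seen: set[str] = set()
    classes = list(_CLASS_WEIGHTS)
    while len(keys) < n_lipids:
        cls = classes[int(rng.integers(len(classes)))]
        name = _random_name(cls, rng)
        key = canonical_key(parse_lipid_name(name))
        if key not in seen:
            seen.add(key)
            keys.append(name)

    kinds = (
        ["rt_twin"] * scheme.get("rt_twin", 0)
        + ["satellite"] * scheme.get("satellite", 0)
        + ["dual_mode"] * scheme.get("dual_mode", 0)
    )
    kinds += ["unique"] * (n_lipids - len(kinds))

    positive: list[FeatureAnnotation] = []
    negative: list[FeatureAnnotation] = []
    survivors: list[FeatureAnnotation] = []

    def emit(ann: FeatureAnnotation, survive: bool) -> None:
        (positive if ann.mode == "positive" else negative).append(ann)
        if survive:
            survivors.append(ann)

    for name, kind in zip(keys, kinds):
        lipid = parse_lipid_name(name)
        mode = "positive" if rng.random() < 0.6 else "negative"
        rt = float(rng.uniform(1.0, 14.0))
        ab = float(rng.lognormal(np.log(1e5), 1.0))
        base = FeatureAnnotation(lipid, mode, rt, ab)
        emit(base, survive=True)
        if kind == "rt_twin":
            twin = FeatureAnnotation(
                lipid, mode, rt + float(rng.uniform(0.01, 0.095)),
                ab * float(rng.uniform(0.30, 0.90)),
            )
            emit(twin, survive=False)
        elif kind == "satellite":
            sat = FeatureAnnotation(
                lipid, mode, rt + float(rng.uniform(0.15, 1.0)),
                ab * float(rng.uniform(0.05, 0.20)),
            )
            emit(sat, survive=False)
        elif kind == "dual_mode":
            other = "negative" if mode == "positive" else "positive"
            dup = FeatureAnnotation(
                lipid, other, float(rng.uniform(1.0, 14.0)),
                ab * float(rng.uniform(0.30, 0.90)),
            )
            emit(dup, survive=False)

    return AnnotationFixture(positive=positive, negative=negative, survivors=survivors)


# --------------------------------------------------------------------------
# recovery evaluation


@dataclass
class RecoveryMetrics:
    """How well the screen recovered the planted contributor structure."""

    sensitivity: float | None  # flagged & planted / planted (None if nothing planted)
    false_flag_rate: float | None
    sign_accuracy: float | None  # among correctly flagged links
    top_tissue: str | None  # tissue with most flagged positive predictors
    contributor_top_ranked: bool
    n_planted: int
    n_null: int


def evaluate_recovery(records: pd.DataFrame, truth: GroundTruth) -> RecoveryMetrics:
    """Score screen output (``regression.screen_plasma_lipid`` rows, possibly
    concatenated over targets) against the planted ground truth."""
    if records.empty:
        raise ValueError("no screen records to evaluate")
    unknown = set(records["plasma_lipid"]) - set(truth.targets)
    if unknown:
        raise ValueError(f"records reference targets not in this ground truth: {sorted(unknown)}")

    planted = {
        (r.tissue, r.tissue_lipid, r.plasma_lipid): r.beta2
        for r in truth.links.itertuples()
    }
    idx = list(zip(records["tissue"], records["tissue_lipid"], records["plasma_lipid"]))
    is_planted = np.array([t in planted for t in idx])
    flagged = records["significant"].to_numpy(dtype=bool)

    n_planted = int(is_planted.sum())
    n_null = int((~is_planted).sum())
    sensitivity = float(flagged[is_planted].mean()) if n_planted else None
    false_rate = float(flagged[~is_planted].mean()) if n_null else None

    hit = flagged & is_planted
    if hit.any():
        true_sign = np.array([np.sign(planted[t]) if t in planted else 0.0 for t in idx])
        obs_sign = np.where(records["predictor_sign"].to_numpy() == "positive", 1.0, -1.0)
        sign_acc = float((obs_sign[hit] == true_sign[hit]).mean())
    else:
        sign_acc = None

    pos_flagged = records.loc[flagged & (records["predictor_sign"] == "positive")]
    if len(pos_flagged):
        counts = pos_flagged.groupby("tissue").size().sort_values(ascending=False)
        top = str(counts.index[0])
        top_ranked = bool(
            top == truth.contributor_tissue
            and (len(counts) == 1 or counts.iloc[0] > counts.iloc[1])
        )
    else:
        top, top_ranked = None, False

    return RecoveryMetrics(
        sensitivity=sensitivity,
        false_flag_rate=false_rate,
        sign_accuracy=sign_acc,
        top_tissue=top,
        contributor_top_ranked=top_ranked,
        n_planted=n_planted,
        n_null=n_null,
    )
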