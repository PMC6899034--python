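"""Synthetic screening-campaign generator.

Emulates a bortezomib-suppressor growth screen in NGLY1-deficient
invertebrates: arrested mutant larvae in negative-control wells, fully
grown (progeny-bearing) animals in positive-control wells, and test
compounds drawn from ground-truth effect classes —

* ``inactive`` — no effect on growth;
* ``suppressor`` — restores a fraction of full growth in drugged mutants;
* ``enhancer_toxic`` — further reduces growth below the arrest baseline;
* ``bzb_inactivator`` — chemically neutralizes bortezomib, so rescue
  appears only in bortezomib-containing paradigms (a chemical false
  positive, not a biological suppressor);
* ``species_restricted`` — a suppressor whose target is not conserved,
  active in one species only.

Every generated artifact (truth table, plate layouts, well measurements,
dose-response series, validation outcomes) is a pandas DataFrame keyed by
the campaign seed; regeneration with the same seed is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    BZB_PARADIGMS,
    EFFECT_CLASSES,
    INVERTEBRATE_PARADIGMS,
    CampaignConfig,
    CascadeConfig,
    PlateFormat,
)
from .doseresponse import four_pl
from .errors import ConfigError

TRUTH_COLUMNS = [
    "compound_id",
    "effect_class",
    "rescue_fraction",
    "toxicity_fraction",
    "active_species",
    "nrf2_ec50_uM",
]
LAYOUT_COLUMNS = [
    "plate_id", "well", "row", "col", "role", "compound_id", "dose",
    "dose_unit", "replicate",
]


@dataclass(frozen=True)
class CompoundEffect:
    """Ground-truth behaviour of one library compound."""

    compound_id: str
    effect_class: str
    rescue_fraction: float = 0.0
    toxicity_fraction: float = 0.0
    active_species: frozenset = frozenset({"worm", "fly"})
    nrf2_ec50_uM: float | None = None

    def __post_init__(self) -> None:
        if self.effect_class not in EFFECT_CLASSES:
            raise ConfigError(f"unknown effect class {self.effect_class!r}")
        if not 0.0 <= self.rescue_fraction <= 1.0:
            raise ConfigError("rescue_fraction must be in [0, 1]")
        if not 0.0 <= self.toxicity_fraction <= 1.0:
            raise ConfigError("toxicity_fraction must be in [0, 1]")
        if self.effect_class == "inactive" and (
            self.rescue_fraction != 0 or self.toxicity_fraction != 0
        ):
            raise ConfigError("inactive compounds must have zero effect sizes")
        if self.effect_class in ("suppressor", "bzb_inactivator", "species_restricted"):
            if self.rescue_fraction <= 0:
                raise ConfigError(f"{self.effect_class} requires rescue_fraction > 0")
        if self.effect_class == "enhancer_toxic" and self.toxicity_fraction <= 0:
            raise ConfigError("enhancer_toxic requires toxicity_fraction > 0")

    def active_in(self, paradigm: str) -> bool:
        """Does this compound rescue growth in the given assay paradigm?"""
        if self.effect_class in ("suppressor", "species_restricted"):
            species = "worm" if paradigm.startswith("worm") else "fly"
            return species in self.active_species
        if self.effect_class == "bzb_inactivator":
            return paradigm in BZB_PARADIGMS
        return False


@dataclass
class DoseSeries:
    """One dose-response experiment: doses × replicate response matrix."""

    genotype: str
    drug: str
    doses: np.ndarray            # strictly increasing, ≥ 0
    responses: np.ndarray        # shape (n_doses, n_reps), area AU
    dose_unit: str = "nM"

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.atleast_2d(np.asarray(self.responses, dtype=float))
        if self.responses.shape[0] != self.doses.shape[0]:
            self.responses = self.responses.T
        if np.any(self.doses < 0):
            raise ConfigError("doses must be non-negative")
        if np.any(np.diff(self.doses) <= 0):
            raise ConfigError("doses must be strictly increasing")
        if np.any(self.responses < 0):
            raise ConfigError("responses must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        n_reps = self.responses.shape[1]
        return pd.DataFrame({
            "genotype": self.genotype,
            "drug": self.drug,
            "dose": np.repeat(self.doses, n_reps),
            "dose_unit": self.dose_unit,
            "replicate": np.tile(np.arange(1, n_reps + 1), len(self.doses)),
            "response": self.responses.ravel(),
        })


@dataclass
class CampaignTruth:
    """Ground truth of a simulated campaign plus its configuration."""

    config: CampaignConfig
    effects: pd.DataFrame = field(repr=False)

    def effect(self, compound_id: str) -> CompoundEffect:
        row = self.effects.loc[self.effects.compound_id == compound_id]
        if row.empty:
            raise KeyError(compound_id)
        return _row_to_effect(row.iloc[0])


def _row_to_effect(row: pd.Series) -> CompoundEffect:
    ec50 = row["nrf2_ec50_uM"]
    return CompoundEffect(
        compound_id=row["compound_id"],
        effect_class=row["effect_class"],
        rescue_fraction=float(row["rescue_fraction"]),
        toxicity_fraction=float(row["toxicity_fraction"]),
        active_species=frozenset(str(row["active_species"]).split("|")),
        nrf2_ec50_uM=None if pd.isna(ec50) else float(ec50),
    )


def draw_effects(config: CampaignConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw one :class:`CompoundEffect` per compound from the class mixture."""
    n = config.n_compounds
    classes = [c for c in EFFECT_CLASSES if config.class_mixture.get(c, 0) > 0]
    probs = np.array([config.class_mixture[c] for c in classes])
    idx = rng.choice(len(classes), size=n, p=probs / probs.sum())
    cls = np.array(classes, dtype=object)[idx]

    lo, hi = config.rescue_range
    rescue = rng.uniform(lo, hi, size=n)
    tlo, thi = config.toxicity_range
    tox = rng.uniform(tlo, thi, size=n)
    species = np.where(rng.random(n) < 0.5, "worm", "fly")
    nrf2_draw = rng.random(n)
    elo, ehi = config.nrf2_ec50_range_uM
    nrf2_ec50 = np.exp(rng.uniform(np.log(elo), np.log(ehi), size=n))

    rescuing = np.isin(cls, ("suppressor", "bzb_inactivator", "species_restricted"))
    rescue = np.where(rescuing, rescue, 0.0)
    tox = np.where(cls == "enhancer_toxic", tox, 0.0)
    active_species = np.where(cls == "species_restricted", species, "worm|fly")
    # only genuine suppressors can act through NRF2 in the reporter line
    has_nrf2 = (cls == "suppressor") & (nrf2_draw < config.nrf2_active_fraction)
    nrf2 = np.where(has_nrf2, nrf2_ec50, np.nan)

    width = max(4, len(str(n)))
    ids = np.array([f"C{i + 1:0{width}d}" for i in range(n)], dtype=object)
    truth = pd.DataFrame({
        "compound_id": ids,
        "effect_class": cls,
        "rescue_fraction": rescue,
        "toxicity_fraction": tox,
        "active_species": active_species,
        "nrf2_ec50_uM": nrf2,
    })

    if config.plant_all_assay_active:
        truth.loc[0, ["effect_class", "rescue_fraction", "toxicity_fraction",
                      "active_species", "nrf2_ec50_uM"]] = (
            "suppressor", 0.9, 0.0, "worm|fly", 10.0)
        truth.loc[1:, "nrf2_ec50_uM"] = np.nan
    return truth


def plate_roles(fmt: PlateFormat) -> pd.DataFrame:
    """Static per-well role map of one plate (control placement + test wells)."""
    rows, cols = np.meshgrid(
        np.arange(fmt.n_rows), np.arange(fmt.n_cols), indexing="ij"
    )
    rows, cols = rows.ravel(), cols.ravel()
    ctrl_cols = fmt.control_columns()
    left = ctrl_cols[: len(ctrl_cols) // 2]
    role = np.full(rows.shape, "test", dtype=object)
    for i in range(len(rows)):
        c = cols[i]
        if c in ctrl_cols:
            # left columns: even rows positive; right columns: even rows negative
            even = rows[i] % 2 == 0
            if c in left:
                role[i] = "positive" if even else "negative"
            else:
                role[i] = "negative" if even else "positive"
    wells = [fmt.well_id(r, c) for r, c in zip(rows, cols)]
    return pd.DataFrame({"well": wells, "row": rows, "col": cols, "role": role})


def build_campaign(config: CampaignConfig) -> tuple[CampaignTruth, pd.DataFrame]:
    """Build compound truth and triplicate plate layouts for a campaign.

    Compounds are filled into test wells in plate-major, row-major order;
    each replicate reuses the same well assignment on its own physical
    plate (``<format>-P<plate>-R<replicate>``). Unused test wells on the
    last plate get role ``empty``.
    """
    rng = np.random.default_rng(config.seed)
    truth = CampaignTruth(config=config, effects=draw_effects(config, rng))

    fmt = config.format
    roles = plate_roles(fmt)
    test_mask = (roles.role == "test").to_numpy()
    n_test = int(test_mask.sum())
    n_plates = -(-config.n_compounds // n_test)

    frames = []
    compound_ids = truth.effects.compound_id.to_numpy()
    for p in range(n_plates):
        chunk = compound_ids[p * n_test : (p + 1) * n_test]
        plate = roles.copy()
        assigned = np.full(n_test, None, dtype=object)
        assigned[: len(chunk)] = chunk
        col = np.full(len(plate), None, dtype=object)
        col[test_mask] = assigned
        plate["compound_id"] = col
        plate.loc[test_mask & pd.isna(plate.compound_id), "role"] = "empty"
        for rep in range(1, config.n_replicates + 1):
            rep_plate = plate.copy()
            rep_plate.insert(0, "plate_id", f"{fmt.name}-P{p + 1:02d}-R{rep}")
            rep_plate["dose"] = np.where(
                rep_plate.role == "test", config.screening_dose, 0.0
            )
            rep_plate["dose_unit"] = config.screening_dose_unit
            rep_plate["replicate"] = rep
            frames.append(rep_plate)
    layout = pd.concat(frames, ignore_index=True)[LAYOUT_COLUMNS]
    return truth, layout


def _net_rescue(
    role: np.ndarray,
    rescue: np.ndarray,
    toxicity: np.ndarray,
    active: np.ndarray,
) -> np.ndarray:
    """Net growth fraction r for each well (before clamping)."""
    r = np.where(active, rescue, 0.0) - toxicity
    r = np.where(role == "positive", 1.0, r)
    r = np.where(role == "negative", 0.0, r)
    return r


def expected_area(
    role: str | np.ndarray,
    net_rescue: float | np.ndarray,
    config: CampaignConfig,
) -> np.ndarray:
    """Noise-free expected well area: arrest + r·(full − arrest), clamped at 0."""
    span = config.full_area_AU - config.arrest_area_AU
    return np.maximum(0.0, config.arrest_area_AU + np.asarray(net_rescue) * span)


def simulate_well(
    role: str,
    effect: CompoundEffect | None,
    config: CampaignConfig,
    rng: np.random.Generator,
    paradigm: str | None = None,
) -> tuple[float, int]:
    """Simulate a single well; returns ``(total_area, object_count)``.

    ``paradigm`` defaults to the primary screen of the configured plate
    format (``worm_bzb`` or ``fly_het_bzb``).
    """
    if paradigm is None:
        paradigm = "worm_bzb" if config.format.species == "worm" else "fly_het_bzb"
    if role == "test":
        if effect is None:
            raise ConfigError("test well requires a CompoundEffect")
        active = effect.active_in(paradigm)
        r = (effect.rescue_fraction if active else 0.0) - effect.toxicity_fraction
    elif role == "positive":
        r = 1.0
    elif role == "negative":
        r = 0.0
    else:
        raise ConfigError(f"unknown well role {role!r}")
    exp_area = float(expected_area(role, r, config))
    area = float(_apply_noise(np.array([exp_area]), config, rng)[0])
    count = _well_count(np.array([r]), config)[0]
    return area, int(count)


def _apply_noise(
    expected: np.ndarray, config: CampaignConfig, rng: np.random.Generator
) -> np.ndarray:
    if config.noise_sigma == 0:
        return expected.copy()
    if config.noise_model == "lognormal":
        return expected * rng.lognormal(0.0, config.noise_sigma, size=expected.shape)
    return np.maximum(
        0.0, expected * (1.0 + rng.normal(0.0, config.noise_sigma, expected.shape))
    )


def _well_count(net_rescue: np.ndarray, config: CampaignConfig) -> np.ndarray:
    """Deterministic animal count: dispensed larvae plus progeny ∝ growth."""
    animals = config.animals_per_test_well
    progeny = config.format.progeny_per_animal
    r = np.clip(net_rescue, 0.0, 1.0)
    return np.rint(animals * (1.0 + progeny * r)).astype(int)


def simulate_measurements(
    layout: pd.DataFrame,
    truth: CampaignTruth,
    rng: np.random.Generator,
    paradigm: str | None = None,
) -> pd.DataFrame:
    """Vectorized well simulation for a full layout table.

    Returns a measurement table (plate_id, well, total_area, object_count,
    normalized_area, artifact, artifact_reason) covering every non-empty
    well of the layout.
    """
    config = truth.config
    if paradigm is None:
        paradigm = "worm_bzb" if config.format.species == "worm" else "fly_het_bzb"
    live = layout[layout.role != "empty"].reset_index(drop=True)
    merged = live.merge(truth.effects, on="compound_id", how="left")

    rescue = merged.rescue_fraction.fillna(0.0).to_numpy()
    tox = merged.toxicity_fraction.fillna(0.0).to_numpy()
    cls = merged.effect_class.fillna("inactive").to_numpy()
    species_ok = np.array([
        ("worm" if paradigm.startswith("worm") else "fly") in str(s).split("|")
        for s in merged.active_species.fillna("")
    ])
    active = np.where(
        np.isin(cls, ("suppressor", "species_restricted")), species_ok,
        np.where(cls == "bzb_inactivator", paradigm in BZB_PARADIGMS, False),
    )
    role = merged.role.to_numpy()
    r = _net_rescue(role, rescue, tox, active)
    exp = expected_area(role, r, config)
    area = _apply_noise(exp, config, rng)
    count = _well_count(r, config)

    out = pd.DataFrame({
        "plate_id": merged.plate_id,
        "well": merged.well,
        "total_area": area,
        "object_count": count,
        "normalized_area": np.where(count > 0, area / np.maximum(count, 1), np.nan),
        "artifact": False,
        "artifact_reason": None,
    })
    return out


def simulate_dose_series(
    curve_params: tuple[float, float, float, float] | dict,
    doses,
    n_reps: int,
    noise_sigma: float,
    rng: np.random.Generator,
    genotype: str = "mutant",
    drug: str = "bortezomib",
    dose_unit: str = "nM",
) -> DoseSeries:
    """Simulate a 4PL dose-response series with lognormal response noise.

    ``curve_params`` is ``(bottom, top, ec50, hill)``; dose 0 is allowed
    and maps to the top asymptote.
    """
    if isinstance(curve_params, dict):
        bottom, top, ec50, hill = (
            curve_params["bottom"], curve_params["top"],
            curve_params["ec50"], curve_params["hill"],
        )
    else:
        bottom, top, ec50, hill = curve_params
    if ec50 <= 0:
        raise ConfigError(f"ec50 must be positive, got {ec50}")
    doses = np.asarray(doses, dtype=float)
    expected = four_pl(doses, bottom, top, ec50, hill)
    resp = np.repeat(expected[:, None], n_reps, axis=1)
    if noise_sigma > 0:
        resp = resp * rng.lognormal(0.0, noise_sigma, size=resp.shape)
    return DoseSeries(
        genotype=genotype, drug=drug, doses=doses,
        responses=resp, dose_unit=dose_unit,
    )


def simulate_validation_outcomes(
    truth: CampaignTruth,
    compound_ids,
    rng: np.random.Generator,
    cascade_config: CascadeConfig | None = None,
    ec50_noise_sigma: float = 0.1,
) -> pd.DataFrame:
    """Simulate retest/cross-test outcomes for the validation cascade.

    Each listed compound is retested in the four invertebrate paradigms
    (pass iff its noisy observed rescue fraction clears the configured
    threshold) and in the NRF2 reporter (a measured EC50 is attached when
    the compound is a true reporter activator; otherwise the compound is
    recorded as tested with no potency, i.e. fail).
    """
    cascade_config = cascade_config or CascadeConfig()
    cfg = truth.config
    records = []
    eff = truth.effects.set_index("compound_id")
    for cid in compound_ids:
        row = eff.loc[cid]
        effect = CompoundEffect(
            compound_id=cid,
            effect_class=row["effect_class"],
            rescue_fraction=float(row["rescue_fraction"]),
            toxicity_fraction=float(row["toxicity_fraction"]),
            active_species=frozenset(str(row["active_species"]).split("|")),
            nrf2_ec50_uM=None if pd.isna(row["nrf2_ec50_uM"]) else float(row["nrf2_ec50_uM"]),
        )
        for paradigm in INVERTEBRATE_PARADIGMS:
            r_true = effect.rescue_fraction if effect.active_in(paradigm) else 0.0
            observed = r_true * rng.lognormal(0.0, cfg.noise_sigma) if r_true else 0.0
            records.append({
                "compound_id": cid,
                "paradigm": paradigm,
                "dose": cfg.screening_dose,
                "result": "pass" if observed >= cascade_config.pass_rescue_threshold
                          else "fail",
                "ec50_uM": np.nan,
            })
        if effect.nrf2_ec50_uM is not None:
            measured = effect.nrf2_ec50_uM * rng.lognormal(0.0, ec50_noise_sigma)
        else:
            measured = np.nan
        lo, hi = cascade_config.nrf2_window_uM
        in_window = (not np.isnan(measured)) and measured <= hi and (
            not cascade_config.nrf2_lower_exclusionary or measured >= lo
        )
        records.append({
            "compound_id": cid,
            "paradigm": "nrf2_reporter",
            "dose": np.nan,
            "result": "pass" if in_window else "fail",
            "ec50_uM": measured,
        })
    return pd.DataFrame.from_records(records)
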