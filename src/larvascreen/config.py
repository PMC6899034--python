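"""Campaign and pipeline configuration models.

Configurations are pydantic models with ``extra="forbid"`` so a typo in a
YAML key fails before any stage runs. Plate geometry is fixed per format:

* ``worm384`` — 384-well plate (rows A–P, columns 1–24), 32 positive and
  32 negative control wells, 15 L1 larvae dispensed per test well. The
  growth readout is total organism area per well; fully grown wells
  include a progeny amplification over the arrested-larva baseline.
* ``fly96`` — 96-well plate (rows A–H, columns 1–12), 8 positive and 8
  negative control wells, 3 first-instar larvae per test well; area is
  normalized by larva count downstream.

Control wells occupy the two leftmost and two rightmost columns,
alternating positive/negative down each column so both roles sample the
full row range of the plate.
"""

from __future__ import annotations

import math
import string
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigError

EFFECT_CLASSES = (
    "inactive",
    "suppressor",
    "enhancer_toxic",
    "bzb_inactivator",
    "species_restricted",
)

#: Validation-cascade assay paradigms. ``*_bzb`` paradigms contain
#: bortezomib and are therefore vulnerable to chemical drug inactivation.
PARADIGMS = ("worm_bzb", "worm_czb", "fly_het_bzb", "fly_homo_nodrug", "nrf2_reporter")
BZB_PARADIGMS = frozenset({"worm_bzb", "fly_het_bzb"})
INVERTEBRATE_PARADIGMS = ("worm_bzb", "worm_czb", "fly_het_bzb", "fly_homo_nodrug")


class PlateFormat(BaseModel):
    """Immutable plate geometry."""

    model_config = ConfigDict(frozen=True)

    name: str
    n_rows: int
    n_cols: int
    n_pos_controls: int
    n_neg_controls: int
    animals_per_test_well: int
    species: Literal["worm", "fly"]
    progeny_per_animal: int

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_test_wells(self) -> int:
        return self.n_wells - self.n_pos_controls - self.n_neg_controls

    def well_id(self, row: int, col: int) -> str:
        """Letter-number well ID, e.g. ``A01`` … ``P24``."""
        return f"{string.ascii_uppercase[row]}{col + 1:02d}"

    def control_columns(self) -> tuple[int, ...]:
        n_ctrl_cols = (self.n_pos_controls + self.n_neg_controls) // self.n_rows
        half = n_ctrl_cols // 2
        return tuple(range(half)) + tuple(range(self.n_cols - half, self.n_cols))


PLATE_FORMATS: dict[str, PlateFormat] = {
    "worm384": PlateFormat(
        name="worm384", n_rows=16, n_cols=24,
        n_pos_controls=32, n_neg_controls=32,
        animals_per_test_well=15, species="worm", progeny_per_animal=9,
    ),
    "fly96": PlateFormat(
        name="fly96", n_rows=8, n_cols=12,
        n_pos_controls=8, n_neg_controls=8,
        animals_per_test_well=3, species="fly", progeny_per_animal=0,
    ),
}


class CampaignConfig(BaseModel):
    """Parameters of one synthetic screening campaign.

    Defaults model the worm primary screen: a 2560-compound library
    screened in triplicate at 25 µM on 384-well plates, negative controls
    arrested at ``arrest_area_AU`` by 205 nM bortezomib and positive
    controls grown to ``full_area_AU`` (progeny included). Well noise is
    multiplicative lognormal with scale ``noise_sigma`` so areas stay
    positive and spread scales with growth.
    """

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    n_compounds: int = 2560
    class_mixture: dict[str, float] = Field(
        default_factory=lambda: {"inactive": 1.0}
    )
    plate_format: Literal["worm384", "fly96"] = "worm384"
    n_replicates: int = 3
    controls_per_plate: Optional[tuple[int, int]] = None  # (positive, negative)
    animals_per_test_well: Optional[int] = None
    noise_sigma: float = 0.15
    noise_model: Literal["lognormal", "gaussian"] = "lognormal"
    arrest_area_AU: float = 500.0
    full_area_AU: float = 5000.0
    screening_dose: float = 25.0
    screening_dose_unit: str = "uM"
    # effect-class draw ranges
    rescue_range: tuple[float, float] = (0.5, 1.0)
    toxicity_range: tuple[float, float] = (0.05, 0.3)
    nrf2_active_fraction: float = 0.15
    nrf2_ec50_range_uM: tuple[float, float] = (2.0, 30.0)
    #: force compound 0 to be a dual-species suppressor with an in-window
    #: NRF2 EC50 and deny in-window EC50s to every other compound — used to
    #: exercise the all-assay-active end of the validation cascade.
    plant_all_assay_active: bool = False

    @model_validator(mode="after")
    def _validate(self) -> "CampaignConfig":
        fmt = PLATE_FORMATS[self.plate_format]
        if self.controls_per_plate is None:
            object.__setattr__(
                self, "controls_per_plate", (fmt.n_pos_controls, fmt.n_neg_controls)
            )
        if self.animals_per_test_well is None:
            object.__setattr__(
                self, "animals_per_test_well", fmt.animals_per_test_well
            )
        if self.n_compounds <= 0:
            raise ConfigError(f"n_compounds must be positive, got {self.n_compounds}")
        if self.n_replicates <= 0:
            raise ConfigError("n_replicates must be positive")
        unknown = set(self.class_mixture) - set(EFFECT_CLASSES)
        if unknown:
            raise ConfigError(f"unknown effect classes in mixture: {sorted(unknown)}")
        if any(p < 0 for p in self.class_mixture.values()):
            raise ConfigError("class_mixture entries must be non-negative")
        total = sum(self.class_mixture.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigError(f"class_mixture must sum to 1 (got {total!r})")
        if not (self.full_area_AU > self.arrest_area_AU > 0):
            raise ConfigError(
                "requires full_area_AU > arrest_area_AU > 0, got "
                f"{self.full_area_AU} / {self.arrest_area_AU}"
            )
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be non-negative")
        return self

    @property
    def format(self) -> PlateFormat:
        fmt = PLATE_FORMATS[self.plate_format]
        if (
            self.controls_per_plate == (fmt.n_pos_controls, fmt.n_neg_controls)
            and self.animals_per_test_well == fmt.animals_per_test_well
        ):
            return fmt
        return fmt.model_copy(
            update={
                "n_pos_controls": self.controls_per_plate[0],
                "n_neg_controls": self.controls_per_plate[1],
                "animals_per_test_well": self.animals_per_test_well,
            }
        )


class SegmentationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    opening_radius: int = 1
    min_object_px: int = 9
    expected_animal_px: float = 100.0
    max_object_factor: float = 20.0      # × expected_animal_px → oversized artifact
    max_total_area_fraction: float = 0.5  # of image pixels → implausible well
    max_border_fraction: float = 0.25     # foreground on >25% of border px


class ConsensusRuleConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    z_threshold: float
    comparison: Literal["ge", "gt", "le"]
    min_replicates: int
    n_replicates: int = 3


class DoseResponseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    target_reduction: float = 0.85
    ec50_bounds_factor: float = 100.0


class CascadeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    nrf2_window_uM: tuple[float, float] = (2.0, 30.0)
    nrf2_lower_exclusionary: bool = False
    pass_rescue_threshold: float = 0.3
    precision: int = 0


class PipelineConfig(BaseModel):
    """Top-level config for :func:`larvascreen.pipeline.run_pipeline`."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    out_dir: str = "results"
    log_level: str = "INFO"
    render_images: bool = False
    image_shape: tuple[int, int] = (96, 96)
    campaign: CampaignConfig = Field(default_factory=CampaignConfig)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    dose_response: DoseResponseConfig = Field(default_factory=DoseResponseConfig)
    cascade: CascadeConfig = Field(default_factory=CascadeConfig)
    qc_min_separation: float = 3.0
    qc_max_eliminated_fraction: float = 0.25
    outlier_side: Literal["both", "upper"] = "both"
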