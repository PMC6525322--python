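"""Model parameters and configuration I/O.

All network constants live in a single flat :class:`ModelParams` record:
population sizes, the rate nonlinearity, lateral inhibition, the Hebbian
learning rate and weight normalization, drive magnitudes, per-step noise,
and the canonical epoch durations used by the trial builders.  Parameters
are dimensionless; time is counted in simulation steps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

VARIANTS = (
    "full",
    "facilitation_only",
    "no_c_to_f_plasticity",
    "no_conjunctive_layer",
)

DIMENSION_NAMES = ("color", "orientation", "location")


class ConfigurationError(ValueError):
    """Raised for invalid or infeasible parameter settings."""


@dataclass
class ModelParams:
    """Constants of the plastic-attractor network.

    The canonical network has three feature dimensions (color, orientation,
    location) with four feature-selective units each, plus four freely
    conjunctive units coupled to the feature layer by two rapidly plastic
    weight matrices.
    """

    # architecture
    n_dims: int = 3
    n_feat_per_dim: int = 4
    n_conj: int = 4
    variant: str = "full"

    # rate dynamics
    tau: float = 10.0            # rate relaxation time constant, steps
    gain: float = 8.0            # slope of the logistic nonlinearity
    threshold: float = 0.5       # midpoint of the logistic nonlinearity
    beta_f: float = 0.6          # within-dimension inhibition, feature layer
    beta_c: float = 1.2          # lateral inhibition, conjunctive layer
    noise_sigma: float = 0.02    # per-step Gaussian drive noise, std

    # plasticity
    eta: float = 0.05            # Hebbian learning rate per step
    hebbian_gate: float = 0.1    # postsynaptic rate below which a row does not learn
    w_floor: float = 0.0         # baseline connectivity: weights never erode below this
    w_init_scale: float = 0.01   # std of initial weight jitter
    w_norm: float = 1.0          # norm of each unit's incoming weight row

    # drives
    stim_drive: float = 1.0      # external input during stimulus/cue/probe
    reset_drive: float = 1.0     # magnitude of the inter-trial inhibitory reset
    readout_threshold: float = 0.5
    # abrupt display changes (cue, probe) interrupt ongoing activity with a
    # brief inhibitory onset transient before their input switches on
    onset_quench: bool = True
    # new stimuli transiently inhibit the conjunctive layer (feedforward
    # onset inhibition) so the conjunctive competition restarts on the new
    # feature pattern instead of being held by the previous winner
    stim_onset_steps: int = 20
    stim_onset_drive: float = 2.0

    # short-term facilitation (facilitation_only variant)
    facil_U: float = 0.2
    facil_tau: float = 150.0
    facil_gain: float = 1.0

    # canonical epoch durations, in steps
    stim_steps: int = 50
    gap_steps: int = 10
    delay_steps: int = 200
    cue_steps: int = 30
    pulse_steps: int = 10
    probe_steps: int = 100
    readout_steps: int = 50
    readout_tail: int = 20
    reset_steps: int = 10
    quench_steps: int = 15       # duration of the cue/probe onset transient
    iti_steps: int = 50

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigurationError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )
        for name in ("n_dims", "n_feat_per_dim", "n_conj"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.tau <= 0:
            raise ConfigurationError("tau must be > 0")
        if self.eta < 0:
            raise ConfigurationError("eta must be >= 0")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if self.w_norm <= 0:
            raise ConfigurationError("w_norm must be > 0")
        if self.w_init_scale < 0:
            raise ConfigurationError("w_init_scale must be >= 0")

    # -- derived -----------------------------------------------------------

    @property
    def n_features(self) -> int:
        return self.n_dims * self.n_feat_per_dim

    def feature_index(self, dim: int, feat: int) -> int:
        """Flat unit index under the dimension-major layout."""
        if not (0 <= dim < self.n_dims and 0 <= feat < self.n_feat_per_dim):
            raise ConfigurationError(f"feature ({dim},{feat}) out of range")
        return dim * self.n_feat_per_dim + feat

    def dimension_slice(self, dim: int) -> slice:
        return slice(dim * self.n_feat_per_dim, (dim + 1) * self.n_feat_per_dim)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParams":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yml", ".yaml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def config_hash(self) -> str:
        """Short stable hash identifying this configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def canonical_params(**overrides) -> ModelParams:
    """The calibrated canonical configuration shipped with the package."""
    with resources.files("plastwm").joinpath("canonical.yaml").open() as fh:
        data = yaml.safe_load(fh)
    data.update(overrides)
    return ModelParams.from_dict(data)
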