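"""Visual stimulation protocol: the orientation × spatial-frequency trial grid.

The default protocol is a drifting sinusoidal grating battery: 12 directions
in 30° steps, six spatial frequencies, 1.5 s presentations at 2 Hz temporal
frequency, five repeats per eye, with two grey blank conditions per eye used
to estimate spontaneous firing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["StimulusProtocol", "make_stimulus_protocol", "ProtocolError"]

EYES = ("contra", "ipsi")


class ProtocolError(ValueError):
    """Raised when a stimulus-protocol field violates its invariants."""


@dataclass(frozen=True)
class StimulusProtocol:
    """Grid of grating conditions presented to each eye.

    Attributes
    ----------
    orientations_deg
        Drift directions in degrees, strictly increasing, equally spaced,
        in [0, 360).
    spatial_frequencies_cpd
        Grating spatial frequencies in cycles/degree, all positive.
    temporal_frequency_hz
        Drift temporal frequency.
    stim_duration_s
        Presentation duration of each trial.
    repeats_per_eye
        Number of repeats of each condition per eye.
    n_blank_conditions
        Number of grey blank conditions included per eye per repeat block.
    eyes
        Eye labels; analysis assumes ("contra", "ipsi").
    """

    orientations_deg: tuple = tuple(range(0, 360, 30))
    spatial_frequencies_cpd: tuple = (0.01, 0.02, 0.04, 0.08, 0.16, 0.32)
    temporal_frequency_hz: float = 2.0
    stim_duration_s: float = 1.5
    repeats_per_eye: int = 5
    n_blank_conditions: int = 2
    eyes: tuple = EYES

    def __post_init__(self):
        ori = np.asarray(self.orientations_deg, dtype=float)
        if ori.size < 2 or np.any(np.diff(ori) <= 0):
            raise ProtocolError("orientations_deg must be strictly increasing")
        if not np.allclose(np.diff(ori), ori[1] - ori[0]):
            raise ProtocolError("orientations_deg must be equally spaced")
        if ori[0] < 0 or ori[-1] >= 360:
            raise ProtocolError("orientations_deg must lie in [0, 360)")
        sfs = np.asarray(self.spatial_frequencies_cpd, dtype=float)
        if np.any(sfs <= 0):
            raise ProtocolError("spatial_frequencies_cpd must be > 0")
        if self.stim_duration_s <= 0:
            raise ProtocolError("stim_duration_s must be > 0")
        if self.temporal_frequency_hz <= 0:
            raise ProtocolError("temporal_frequency_hz must be > 0")
        if self.repeats_per_eye < 1:
            raise ProtocolError("repeats_per_eye must be >= 1")
        if self.n_blank_conditions < 0:
            raise ProtocolError("n_blank_conditions must be >= 0")

    @property
    def orientation_step_deg(self) -> float:
        ori = self.orientations_deg
        return float(ori[1] - ori[0])

    @property
    def n_stimulus_trials(self) -> int:
        """Total grating trials across both eyes."""
        return (
            len(self.orientations_deg)
            * len(self.spatial_frequencies_cpd)
            * self.repeats_per_eye
            * len(self.eyes)
        )

    @property
    def n_blank_trials(self) -> int:
        return self.n_blank_conditions * self.repeats_per_eye * len(self.eyes)


def make_stimulus_protocol(overrides: dict | None = None) -> StimulusProtocol:
    """Build the default stimulus protocol, optionally overriding fields.

    Parameters
    ----------
    overrides
        Mapping of field name to replacement value. Values are validated
        against the protocol invariants; an invalid value raises
        :class:`ProtocolError` naming the offending field.
    """
    proto = StimulusProtocol()
    if not overrides:
        return proto
    unknown = set(overrides) - set(proto.__dataclass_fields__)
    if unknown:
        raise ProtocolError(f"unknown protocol fields: {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, (list, np.ndarray)) else v
        for k, v in overrides.items()
    }
    return replace(proto, **coerced)
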