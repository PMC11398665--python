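"""LNLN(P) ganglion-cell model.

Cascade: linear Gaussian (or cosine) subunit filters -> subunit
nonlinearity (half-wave rectification, optionally threshold-quadratic)
-> weighted pooling across one or more subunit layouts -> output gain ->
Poisson spike generation.  Optionally an upstream photoreceptor stage
(Gaussian pooling, piecewise-linear nonlinearity with slope 0.5 below
zero) or a temporal filter at 60 Hz.

The output gain anchors the full cascade so that a full-field white
flash (+1 contrast everywhere) yields `output_anchor` expected spikes
(default 30); gray yields `baseline_rate`.  This re-anchoring is applied
per model variant, which is what makes e.g. the threshold-quadratic
variant respond more weakly to sub-maximal stimuli.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .layout import PhotoreceptorStage, SubunitLayout, layout_filter_matrix, subunit_filter
from .stimuli import full_field

__all__ = [
    "GanglionModel",
    "subunit_linear_response",
    "model_rate",
    "model_spikes",
    "photoreceptor_transform",
    "subunit_nonlinearity_apply",
    "receptive_field_map",
    "model_rate_sequence",
    "default_temporal_filter",
]

_NONLINEARITIES = ("rectified-linear", "threshold-quadratic")


def photoreceptor_transform(x):
    """Piecewise-linear photoreceptor nonlinearity: slope 0.5 below 0."""
    x = np.asarray(x, dtype=float)
    return np.where(x < 0, 0.5 * x, x)


def subunit_nonlinearity_apply(x, kind: str = "rectified-linear"):
    """Half-wave rectification, optionally with squaring of the output."""
    x = np.asarray(x, dtype=float)
    if kind == "rectified-linear":
        return np.maximum(x, 0.0)
    if kind == "threshold-quadratic":
        return np.maximum(x, 0.0) ** 2
    raise ValueError(f"unknown subunit nonlinearity {kind!r}")


@dataclass
class GanglionModel:
    layouts: list[SubunitLayout]
    subunit_nonlinearity: str = "rectified-linear"
    output_anchor: float = 30.0
    baseline_rate: float = 0.0
    photoreceptor_stage: PhotoreceptorStage | None = None
    temporal_filter: np.ndarray | None = None
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if isinstance(self.layouts, SubunitLayout):
            self.layouts = [self.layouts]
        if not self.layouts:
            raise ValueError("model needs at least one subunit layout")
        if self.subunit_nonlinearity not in _NONLINEARITIES:
            raise ValueError(
                f"unknown subunit nonlinearity {self.subunit_nonlinearity!r}"
            )
        if self.photoreceptor_stage is not None and len(self.layouts) != 1:
            raise ValueError("photoreceptor stage supports a single layout")
        sizes = {ly.arena_size for ly in self.layouts}
        if len(sizes) != 1:
            raise ValueError("all layouts must share the arena size")
        self.arena_size = sizes.pop()

    # -- cached linear algebra ------------------------------------------------

    def _filters(self):
        if "filters" not in self._cache:
            self._cache["filters"] = [layout_filter_matrix(ly) for ly in self.layouts]
        return self._cache["filters"]

    def _phot_filters(self):
        if "phot" not in self._cache:
            stage = self.photoreceptor_stage
            self._cache["phot"] = np.stack(
                [
                    subunit_filter(ph, self.arena_size, "gaussian").ravel()
                    for ph in stage.photoreceptors
                ]
            )
        return self._cache["phot"]

    # -- cascade --------------------------------------------------------------

    def _subunit_activations(self, batch: np.ndarray, layout_idx: int) -> np.ndarray:
        """(n_subunits, n_stimuli) linear activations for one layout."""
        ly = self.layouts[layout_idx]
        pol = np.array([su.polarity for su in ly.subunits], dtype=float)
        if self.photoreceptor_stage is not None:
            phot_act = self._phot_filters() @ batch.T
            act = self.photoreceptor_stage.connection_weights @ photoreceptor_transform(
                phot_act
            )
        else:
            act = self._filters()[layout_idx] @ batch.T
        return pol[:, None] * act

    def _cascade(self, batch: np.ndarray) -> np.ndarray:
        """Pooled (pre-gain) signal for a (n_stimuli, n_px) batch."""
        pooled = np.zeros(batch.shape[0])
        for i, ly in enumerate(self.layouts):
            act = self._subunit_activations(batch, i)
            nl = subunit_nonlinearity_apply(act, self.subunit_nonlinearity)
            pooled += ly.weights @ nl
        return pooled

    @property
    def gain(self) -> float:
        """Output gain anchoring full-field white at `output_anchor`."""
        if "gain" not in self._cache:
            ref = float(
                self._cascade(full_field(1.0, self.arena_size).reshape(1, -1))[0]
            )
            if ref <= 0:
                raise ValueError("cascade does not respond to full-field white; "
                                 "cannot anchor the output gain")
            self._cache["gain"] = self.output_anchor / ref
        return self._cache["gain"]

    def rates(self, batch: np.ndarray) -> np.ndarray:
        """Expected spike counts for a (n_stimuli, n_px) stimulus batch."""
        batch = np.asarray(batch, dtype=float)
        if batch.ndim != 2 or batch.shape[1] != int(round(self.arena_size)) ** 2:
            raise ValueError("stimulus batch does not match the arena size")
        return self.gain * self._cascade(batch) + self.baseline_rate

    def rate(self, stimulus: np.ndarray) -> float:
        return float(self.rates(_flatten(stimulus, self.arena_size)[None, :])[0])

    def spikes(self, stimulus: np.ndarray, rng) -> int:
        rng = np.random.default_rng(rng)
        return int(rng.poisson(self.rate(stimulus)))


def _flatten(stimulus: np.ndarray, arena_size: float) -> np.ndarray:
    stim = np.asarray(stimulus, dtype=float)
    n = int(round(arena_size))
    if stim.shape != (n, n):
        raise ValueError(f"stimulus shape {stim.shape} does not match arena {n}")
    return stim.ravel()


# ---------------------------------------------------------------------------
# functional surface


def subunit_linear_response(layout: SubunitLayout, stimulus: np.ndarray) -> np.ndarray:
    """Linear activation of each subunit: polarity * <filter, stimulus>."""
    flat = _flatten(stimulus, layout.arena_size)
    pol = np.array([su.polarity for su in layout.subunits], dtype=float)
    return pol * (layout_filter_matrix(layout) @ flat)


def model_rate(model: GanglionModel, stimulus: np.ndarray) -> float:
    """Expected spike count elicited by one flashed stimulus."""
    return model.rate(stimulus)


def model_spikes(model: GanglionModel, stimulus: np.ndarray, rng) -> int:
    """Single Poisson spike-count draw at the model rate."""
    return model.spikes(stimulus, rng)


def receptive_field_map(model: GanglionModel) -> np.ndarray:
    """Rate response to individually flashed single white pixels.

    The baseline rate is excluded so the map reflects stimulus-driven
    activity only; all values are >= 0.
    """
    n = int(round(model.arena_size))
    rates = model.rates(np.eye(n * n)) - model.baseline_rate
    return rates.reshape(n, n)


# ---------------------------------------------------------------------------
# temporal extension (60 Hz frames)


def default_temporal_filter(n_frames: int = 8) -> np.ndarray:
    """Biphasic difference-of-gamma kernel at 60 Hz, shorter than 9 frames.

    Normalised so that a stimulus held for 9 frames (150 ms) elicits the
    same summed rectified response as the static model: the sum over the
    rectified convolution of the kernel with a 9-frame boxcar equals 1.
    """
    t = np.arange(n_frames, dtype=float)
    kern = (t / 2.0) ** 2 * np.exp(-t / 1.0) - 0.25 * (t / 4.0) ** 3 * np.exp(-t / 2.0)
    conv = np.convolve(np.ones(9), kern)
    return kern / np.maximum(conv, 0.0).sum()


def model_rate_sequence(model: GanglionModel, frames: np.ndarray) -> np.ndarray:
    """Per-frame expected spike counts for a stimulus sequence.

    The temporal filter is convolved (full mode) with the per-frame
    linear subunit activations before the rest of the cascade, so the
    returned sequence has len(frames) + len(kernel) - 1 entries and
    includes the response tail after stimulus offset.
    """
    if model.temporal_filter is None:
        raise ValueError("model has no temporal filter")
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValueError("frames must be a nonempty (T, n, n) sequence")
    if model.photoreceptor_stage is not None:
        raise ValueError("temporal filtering with a photoreceptor stage "
                         "is not supported")
    kern = np.asarray(model.temporal_filter, dtype=float)
    batch = frames.reshape(frames.shape[0], -1)
    n_out = frames.shape[0] + len(kern) - 1
    pooled = np.zeros(n_out)
    for i, ly in enumerate(model.layouts):
        act = model._subunit_activations(batch, i)  # (n_sub, T)
        conv = np.apply_along_axis(lambda a: np.convolve(a, kern), 1, act)
        nl = subunit_nonlinearity_apply(conv, model.subunit_nonlinearity)
        pooled += ly.weights @ nl
    return model.gain * pooled + model.baseline_rate
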