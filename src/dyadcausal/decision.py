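"""Short-channel-calibrated direction decisions and accuracy scoring.

The signed band-integrated causal value C of a region epoch is compared with
the dyad's short-distance-channel (SDC) baseline Cshort — the mean of the
same measure computed on the SDC blocks over that dyad's trials.  SDCs see
only scalp/systemic physiology, so Cshort estimates the spurious causal
level that motion and shared physiology induce in the absence of any
neural interaction.  With a small half-width epsilon defining the
no-causality band:

    direction = Model->Imitator  if C > Cshort + epsilon,
                Imitator->Model  if C < Cshort - epsilon,
                none             otherwise.

Note the rule is applied to the signed value: a positive C can still yield
Imitator->Model when Cshort is larger — the rule is taken literally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CausalDecision",
    "DEFAULT_EPSILON",
    "decide_direction",
    "short_channel_baseline",
    "accuracy",
]

DEFAULT_EPSILON = 0.0001

M_TO_I = "M_to_I"
I_TO_M = "I_to_M"
NONE = "none"


@dataclass(frozen=True)
class CausalDecision:
    """Direction call for one epoch, with the quantities that produced it."""

    direction: str
    intensity: float
    c_value: float
    c_short: float
    epsilon: float


def decide_direction(c_value: float, c_short: float,
                     epsilon: float = DEFAULT_EPSILON) -> CausalDecision:
    """Apply the SDC-calibrated threshold rule to one signed band value."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if c_value > c_short + epsilon:
        direction = M_TO_I
    elif c_value < c_short - epsilon:
        direction = I_TO_M
    else:
        direction = NONE
    return CausalDecision(direction=direction, intensity=abs(c_value),
                          c_value=c_value, c_short=c_short, epsilon=epsilon)


def short_channel_baseline(sdc_epochs, settings=None, analyze_fn=None) -> float:
    """Mean signed causal value over a dyad's SDC epochs.

    Each SDC epoch goes through the identical normalize -> order-select ->
    fit -> decompose -> (surrogate-mask) -> band-integrate path as the
    region analysis; the baseline is the plain mean of the per-trial signed
    values.  ``analyze_fn(epoch) -> float`` may be injected; by default the
    pipeline's epoch analyzer with ``settings`` is used.

    An empty epoch list is an error: falling back to a zero baseline must be
    an explicit caller choice, never a silent default.
    """
    sdc_epochs = list(sdc_epochs)
    if not sdc_epochs:
        raise ValueError("no SDC epochs: configure decision.sdc_channels or "
                         "pass an explicit zero baseline")
    if analyze_fn is None:
        from .pipeline import PipelineSettings, epoch_band_value

        settings = settings or PipelineSettings()
        analyze_fn = lambda ep: epoch_band_value(ep, settings)  # noqa: E731
    values = [analyze_fn(ep) for ep in sdc_epochs]
    values = [v for v in values if v is not None and np.isfinite(v)]
    if not values:
        raise RuntimeError("no SDC epoch produced a stable causal value")
    return float(np.mean(values))


def accuracy(decisions, truth, condition: str) -> float:
    """Fraction of epochs whose decision matches the ground truth.

    condition="task": correct means direction == M_to_I given a true
    Model->Imitator link.  condition="baseline": correct means the absence
    of a link was detected (direction == none).
    """
    decisions = list(decisions)
    truth = list(truth)
    if not decisions:
        raise ValueError("empty decision list")
    if len(decisions) != len(truth):
        raise ValueError(f"{len(decisions)} decisions vs {len(truth)} truth labels")
    if condition == "task":
        hits = sum(d.direction == M_TO_I for d, t in zip(decisions, truth)
                   if _true_dir(t) == M_TO_I)
        total = sum(_true_dir(t) == M_TO_I for t in truth)
        if total == 0:
            raise ValueError("no task epochs with a true Model->Imitator link")
        return hits / total
    if condition == "baseline":
        return sum(d.direction == NONE for d in decisions) / len(decisions)
    raise ValueError(f"condition must be 'task' or 'baseline', got {condition!r}")


def _true_dir(t) -> str:
    return t.true_direction if hasattr(t, "true_direction") else str(t)
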