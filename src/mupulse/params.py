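"""Ground-truth subject parameters for the synthetic generators.

The generator emulates the phenomena the analyses are built to detect:
a Rolandic (mu) source with alpha and beta spectral peaks whose power is
modulated event-dependently — a transient event-related synchronization
(ERS) after single pulses that follow single pulses, a prolonged
desynchronization (ERD) during and after 7 Hz pulse trains that bleeds
into subsequent trials (hysteresis) — plus a small P60 evoked component,
occipital alpha, ocular artifacts and 1/f channel noise, and a logistic
psychometric observer for the behavioral arm.

Defaults are the study conditions: timing values (ERS ~0.15-0.35 s, ERD
onset ~0.1 s lasting ~1 s past train offset, hysteresis ~2 s, P60 at
60 ms) follow the reported phenomenology; effect magnitudes are free
generator parameters with defaults chosen to give realistic single-trial
signal-to-noise for a 32-channel recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class SubjectParams:
    """Ground truth for one synthetic subject (amplitudes in microvolts)."""

    mu_alpha_freq: float = 10.0          # Hz, mu alpha peak
    mu_beta_freq: float = 20.0           # Hz, mu beta peak
    mu_base_amp: float = 4.0             # uV alpha amplitude of the mu source
    mu_beta_rel: float = 0.6             # beta amplitude relative to alpha
    ers_gain: float = 0.3                # fractional power change, > 0
    erd_gain: float = -0.3               # fractional power change, < 0
    ers_window: tuple[float, float] = (0.15, 0.35)   # s post onset (SaS)
    erd_window: tuple[float, float] = (0.10, 2.00)   # s post train onset
    hysteresis_decay: float = 2.0        # s, train after-effect time constant
    p60_amp: float = 0.4                 # uV evoked component peak
    p60_latency: float = 0.060           # s
    p60_width: float = 0.010             # s, Gaussian FWHM
    occ_alpha_amp: float = 6.0           # uV occipital alpha amplitude
    occ_alpha_freq: float = 10.5         # Hz
    blink_rate: float = 0.2              # Hz, Poisson blink rate
    blink_amp: float = 80.0              # uV at the frontopolar peak
    noise_sd: float = 5.0                # uV per channel (white + 1/f)
    env_wander: float = 0.25             # fractional slow envelope wandering
    supra_erd_gain: float = -0.4         # imposed ERD after supra pulses
    supra_erd_window: tuple[float, float] = (0.10, 0.60)
    # --- psychophysics -------------------------------------------------
    psychometric_threshold: float = 2.0  # mA, 50% detection point
    psychometric_slope: float = 8.0      # 1/mA logistic slope
    false_alarm_rate: float = 0.005      # catch-trial response probability
    effect_shift: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("mu_base_amp", "p60_amp", "occ_alpha_amp", "blink_amp",
                     "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.psychometric_slope <= 0:
            raise ValueError("psychometric_slope must be > 0")
        for name in ("ers_window", "erd_window"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be an increasing interval")

    def with_(self, **kwargs) -> "SubjectParams":
        """Copy with fields replaced."""
        return replace(self, **kwargs)


def sample_subject_params(rng: np.random.Generator,
                          base: SubjectParams | None = None) -> SubjectParams:
    """Draw plausible between-subject variability around ``base``.

    Peak frequencies jitter by ~0.5 Hz, amplitudes by ~15%; effect
    windows and gains are left at the cohort-level ground truth so that
    recovery tests have a single injected value.
    """
    base = base or SubjectParams()
    return base.with_(
        mu_alpha_freq=base.mu_alpha_freq + rng.normal(0, 0.5),
        mu_beta_freq=base.mu_beta_freq + rng.normal(0, 0.8),
        mu_base_amp=base.mu_base_amp * float(rng.uniform(0.85, 1.15)),
        occ_alpha_amp=base.occ_alpha_amp * float(rng.uniform(0.85, 1.15)),
        noise_sd=base.noise_sd * float(rng.uniform(0.9, 1.1)),
        psychometric_threshold=(base.psychometric_threshold
                                * float(rng.uniform(0.8, 1.2))),
    )
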