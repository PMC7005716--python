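"""Synthetic DNA ensembles: the study conditions for classification and
clustering without external structure or simulation data.

Every generator draws helical parameters around explicit regime means
with explicit Gaussian noise and an explicit seed, and reports those
settings in a manifest, so each dataset is fully reproducible and its
effect sizes are known by construction.

Regimes
-------
* Form classification: A-, B- and Z-like step-parameter regimes.  The
  B regime is the crystal-survey mean; the A regime shifts slide/roll/
  rise the way A-DNA does; the Z regime is left-handed (negative mean
  twist).  With the default within-form noise the regimes are separated
  by well over two noise SDs in at least two step parameters.
* Two-state trajectories: frames alternate between the B regime and a
  perturbed regime offset in roll and twist by three noise SDs --
  a stand-in for the two configurational states a DNA duplex visits in
  an ionic-liquid environment.
* Confined vs free ensembles: the same generator with the noise scaled
  down for the confined copy, mimicking attenuated fluctuation.
"""

from __future__ import annotations

import numpy as np

from .cehs import STEP_PARAMETER_NAMES, HelicalParams
from .structures_io import Structure, build_duplex

__all__ = [
    "FORM_REGIMES",
    "STEP_NOISE_SD",
    "make_form_dataset",
    "make_trajectory",
    "make_two_state_trajectory",
    "make_confined_and_free",
]

#: mean step parameters per DNA-form regime
FORM_REGIMES = {
    "A": {"shift": 0.0, "slide": -1.5, "rise": 2.83, "tilt": 0.0, "roll": 9.0, "twist": 31.0},
    "B": {"shift": 0.0, "slide": 0.23, "rise": 3.32, "tilt": 0.0, "roll": 0.6, "twist": 36.0},
    "Z": {"shift": 0.0, "slide": 0.0, "rise": 3.7, "tilt": 0.0, "roll": 0.0, "twist": -30.0},
}

#: within-ensemble thermal noise SD per step parameter (Angstrom / degrees)
STEP_NOISE_SD = {"shift": 0.3, "slide": 0.4, "rise": 0.15, "tilt": 2.0, "roll": 3.0, "twist": 3.0}

#: offsets defining the second configurational state of a two-state trajectory
TWO_STATE_OFFSETS = {"roll": 9.0, "twist": -9.0}  # 3 noise SDs in both parameters

DEFAULT_SEQUENCE_16 = "ATGCATGCATGCATGC"
DEFAULT_SEQUENCE_8 = "ATGCATGC"


def _draw_step_params(rng, means: dict, noise_scale: float = 1.0, n_steps: int = 1):
    draws = []
    for _ in range(n_steps):
        d = {
            name: means.get(name, 0.0) + noise_scale * STEP_NOISE_SD[name] * rng.standard_normal()
            for name in STEP_PARAMETER_NAMES
        }
        draws.append(HelicalParams.from_dict(d))
    return draws


def make_form_dataset(
    n_per_form: int = 10,
    sequence: str = DEFAULT_SEQUENCE_8,
    seed: int = 0,
    noise_scale: float = 1.0,
    forms=("A", "B", "Z"),
):
    """Labelled static duplexes from the three form regimes.

    Returns (structures, labels, manifest).
    """
    rng = np.random.default_rng(seed)
    structures, labels = [], []
    for form in forms:
        means = FORM_REGIMES[form]
        for _ in range(n_per_form):
            steps = _draw_step_params(rng, means, noise_scale, len(sequence) - 1)
            structures.append(build_duplex(sequence, step_params=steps))
            labels.append(form)
    manifest = {
        "n_per_form": n_per_form,
        "sequence": sequence,
        "seed": seed,
        "noise_sd": {k: noise_scale * v for k, v in STEP_NOISE_SD.items()},
        "regimes": {f: FORM_REGIMES[f] for f in forms},
    }
    return structures, labels, manifest


def make_trajectory(
    n_frames: int,
    regime_of_frame,
    sequence: str = DEFAULT_SEQUENCE_16,
    seed: int = 0,
    noise_scale: float = 1.0,
) -> tuple[Structure, dict]:
    """A multi-model duplex whose frame i follows ``regime_of_frame(i)``
    (a dict of step-parameter means)."""
    rng = np.random.default_rng(seed)
    frames = []
    roster = None
    for i in range(n_frames):
        steps = _draw_step_params(rng, regime_of_frame(i), noise_scale, len(sequence) - 1)
        s = build_duplex(sequence, step_params=steps)
        roster = roster or s.atoms
        frames.append(s.coords)
    manifest = {
        "n_frames": n_frames,
        "sequence": sequence,
        "seed": seed,
        "noise_sd": {k: noise_scale * v for k, v in STEP_NOISE_SD.items()},
    }
    return Structure(roster, np.stack(frames)), manifest


def make_two_state_trajectory(
    n_frames: int = 60,
    sequence: str = DEFAULT_SEQUENCE_16,
    seed: int = 0,
    offsets: dict | None = None,
) -> tuple[Structure, dict]:
    """Frames alternating between the B regime and an offset regime.

    The default offsets move roll and twist by three within-state noise
    SDs, large enough that the two states separate on the first
    principal component.
    """
    offsets = TWO_STATE_OFFSETS if offsets is None else offsets
    base = FORM_REGIMES["B"]
    shifted = {**base, **{k: base.get(k, 0.0) + dv for k, dv in offsets.items()}}

    def regime(i):
        return shifted if i % 2 else base

    traj, manifest = make_trajectory(n_frames, regime, sequence, seed)
    manifest.update(
        {"states": {"A": base, "B": shifted}, "offsets": offsets, "assignment": "alternating"}
    )
    return traj, manifest


def make_confined_and_free(
    n_frames: int = 60,
    sequence: str = DEFAULT_SEQUENCE_16,
    seed: int = 0,
    confinement: float = 0.5,
):
    """A single-state ensemble pair: 'confined' has its noise SD scaled by
    ``confinement`` (< 1), 'free' uses the full noise.  Returns
    (confined, free, manifest)."""
    base = FORM_REGIMES["B"]
    confined, m1 = make_trajectory(n_frames, lambda i: base, sequence, seed, noise_scale=confinement)
    free, m2 = make_trajectory(n_frames, lambda i: base, sequence, seed + 1, noise_scale=1.0)
    return confined, free, {"confined": m1, "free": m2, "confinement": confinement}
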