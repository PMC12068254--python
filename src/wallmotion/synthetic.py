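"""Synthetic cohorts of pulsatile 3D wall-point trajectories.

Real 4D-CTA wall trajectories are quasi-periodic, cardiac-driven point
motions.  The generator emulates them with a sum of harmonics of a
fundamental cardiac frequency along random unit directions, plus isotropic
Gaussian jitter, sampled at 100 Hz for 1 s.  Class contrast is controlled by
a single separability parameter delta:

* TW (thin-walled) points get a larger oscillation amplitude — light, thin
  wall regions show high-speed large movements;
* HR (hyperplastic remodeling) points get their jitter suppressed — thick,
  stiff regions move smoothly;
* delta = 0 collapses both classes onto one generating distribution, and
  "hard" patients (emulating patients on whom a plain classifier fails)
  have delta shrunk by a fixed factor so their TW/HR distributions nearly
  coincide.

Unlabeled points interpolate uniformly between the TW and HR parameter sets,
mirroring their role as ambiguous, difficult-to-label wall regions.
Per-patient heterogeneity enters through log-normal amplitude and frequency
multipliers drawn once per patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .exceptions import ConfigError, DataError
from .io import HR, TW, UNLABELED, Trajectory, read_trajectories, write_trajectories

HARD_DELTA_SHRINK = 0.1  # delta multiplier applied to hard patients


@dataclass
class WallMotionParams:
    """Generating parameters for one cohort.

    Units: mm and seconds.  ``separability`` (delta) scales the TW-vs-HR
    parameter gap: the effective TW amplitude gain is
    ``1 + delta * (tw_amplitude_gain - 1)`` and the effective HR jitter
    divisor is ``1 + delta * (hr_smoothness_gain - 1)``, so delta = 0 makes
    the two classes identically distributed.
    """

    fundamental_freq: float = 1.0     # Hz, cardiac rate
    n_harmonics: int = 3
    base_amplitude: float = 0.5       # mm
    tw_amplitude_gain: float = 2.0    # >= 1
    hr_smoothness_gain: float = 3.0   # >= 1
    jitter_sd: float = 0.05           # mm
    separability: float = 1.0         # delta >= 0
    patient_scale_sd: float = 0.15    # sd of log-normal patient multipliers
    duration: float = 1.0             # s
    rate: float = 100.0               # Hz

    def __post_init__(self):
        if self.rate <= 0 or self.duration <= 0:
            raise ConfigError("rate and duration must be positive")
        if self.base_amplitude < 0 or self.jitter_sd < 0 or self.patient_scale_sd < 0:
            raise ConfigError("amplitudes and variances must be non-negative")
        if self.tw_amplitude_gain < 1 or self.hr_smoothness_gain < 1:
            raise ConfigError("class gains must be >= 1")
        if self.separability < 0:
            raise ConfigError("separability must be >= 0")
        if self.n_harmonics < 1:
            raise ConfigError("need at least one harmonic")
        n = self.rate * self.duration
        if abs(n - round(n)) > 1e-9:
            raise ConfigError("rate * duration must be an integer sample count")

    @property
    def n_samples(self) -> int:
        return int(round(self.rate * self.duration))

    def class_parameters(self, mix: float) -> tuple[float, float]:
        """(amplitude gain, jitter sd) at interpolation coordinate ``mix``.

        mix = 1 is the TW parameter set, mix = 0 the HR set.
        """
        d = self.separability
        tw_gain = 1.0 + d * (self.tw_amplitude_gain - 1.0)
        hr_jitter = self.jitter_sd / (1.0 + d * (self.hr_smoothness_gain - 1.0))
        gain = mix * tw_gain + (1.0 - mix) * 1.0
        jitter = mix * self.jitter_sd + (1.0 - mix) * hr_jitter
        return gain, jitter


@dataclass
class PatientFactors:
    """Per-patient latent multipliers (drawn once per patient)."""

    amplitude: float = 1.0
    frequency: float = 1.0
    hard: bool = False


@dataclass
class CohortManifest:
    """Cohort bookkeeping: who was simulated, from which seeds, into which files."""

    master_seed: int
    params: dict
    patient_ids: list
    counts: dict            # patient_id -> {"TW": n, "HR": n, "unlabeled": n}
    factors: dict           # patient_id -> {"amplitude", "frequency", "hard"}
    files: dict = field(default_factory=dict)  # patient_id -> csv path

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "master_seed": self.master_seed,
                    "params": self.params,
                    "patient_ids": list(self.patient_ids),
                    "counts": self.counts,
                    "factors": self.factors,
                    "files": self.files,
                },
                fh,
                sort_keys=True,
            )

    @classmethod
    def from_yaml(cls, path) -> "CohortManifest":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**d)


def _patient_rng(master_seed: int, patient_index: int) -> np.random.Generator:
    """Deterministic per-patient stream derived from (master seed, index)."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(patient_index,))
    )


def simulate_trajectory(
    params: WallMotionParams,
    cls: int,
    patient_factors: PatientFactors | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    point_id: str = "p0",
    patient_id: str = "patient0",
) -> Trajectory:
    """Simulate one wall-point trajectory of class ``cls`` (0 TW / 1 HR / -1).

    Anchor in a 10 mm cube plus ``n_harmonics`` sinusoids of the (patient-
    scaled) cardiac fundamental along random unit directions, amplitudes
    decaying as 1/k, plus isotropic Gaussian jitter.  Deterministic given the
    seed (or the supplied generator).
    """
    if cls not in (TW, HR, UNLABELED):
        raise DataError(f"unknown class {cls!r}")
    if rng is None:
        if seed is None:
            raise ConfigError("a seed (or rng) is required for reproducibility")
        rng = np.random.default_rng(seed)
    pf = patient_factors or PatientFactors()
    delta_eff = params.separability * (HARD_DELTA_SHRINK if pf.hard else 1.0)
    p = (
        params
        if delta_eff == params.separability
        else WallMotionParams(**{**asdict(params), "separability": delta_eff})
    )

    if cls == TW:
        mix = 1.0
    elif cls == HR:
        mix = 0.0
    else:
        mix = rng.uniform(0.0, 1.0)
    gain, jitter = p.class_parameters(mix)

    T = p.n_samples
    t = np.arange(T) / p.rate
    anchor = rng.uniform(0.0, 10.0, size=3)
    freq = p.fundamental_freq * pf.frequency
    disp = np.zeros((T, 3))
    for k in range(1, p.n_harmonics + 1):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        amp = p.base_amplitude * gain * pf.amplitude / k
        phase = rng.uniform(0.0, 2.0 * np.pi)
        disp += amp * np.sin(2.0 * np.pi * k * freq * t + phase)[:, None] * direction
    coords = anchor + disp + rng.normal(scale=jitter, size=(T, 3))
    return Trajectory(
        point_id=point_id, patient_id=patient_id, label=int(cls),
        coords=coords, rate=p.rate,
    )


def simulate_cohort(
    n_patients: int,
    per_patient_counts: dict,
    params: WallMotionParams | None = None,
    hard_fraction: float = 0.0,
    seed: int = 0,
    out_dir=None,
) -> tuple[CohortManifest, list[Trajectory]]:
    """Simulate a labeled cohort; optionally write per-patient CSVs.

    ``per_patient_counts`` maps class names {"TW", "HR", "unlabeled"} to
    per-patient trajectory counts.  The first ``round(hard_fraction *
    n_patients)`` patients (by index) are "hard": their delta is shrunk by
    ``HARD_DELTA_SHRINK``.  Per-patient random streams are derived from the
    master seed and the patient index, so cohorts are bit-stable under
    changes of ``n_patients``.
    """
    if n_patients < 1:
        raise ConfigError("n_patients must be >= 1")
    if not 0.0 <= hard_fraction <= 1.0:
        raise ConfigError("hard_fraction must be in [0, 1]")
    params = params or WallMotionParams()
    counts = {
        "TW": int(per_patient_counts.get("TW", 0)),
        "HR": int(per_patient_counts.get("HR", 0)),
        "unlabeled": int(per_patient_counts.get("unlabeled", 0)),
    }
    if min(counts.values()) < 0:
        raise ConfigError("counts must be non-negative")
    if counts["TW"] == 0 or counts["HR"] == 0:
        import warnings

        warnings.warn(
            "a labeled class has zero trajectories per patient; "
            "per-patient metrics will be degenerate", stacklevel=2,
        )

    n_hard = int(round(hard_fraction * n_patients))
    patient_ids = [f"patient{idx:03d}" for idx in range(n_patients)]
    trajectories: list[Trajectory] = []
    factors: dict = {}
    per_patient_counts_out: dict = {}
    class_spec = [(TW, counts["TW"]), (HR, counts["HR"]), (UNLABELED, counts["unlabeled"])]

    for idx, pid in enumerate(patient_ids):
        rng = _patient_rng(seed, idx)
        pf = PatientFactors(
            amplitude=float(np.exp(rng.normal(scale=params.patient_scale_sd))),
            frequency=float(np.exp(rng.normal(scale=params.patient_scale_sd))),
            hard=idx < n_hard,
        )
        factors[pid] = {"amplitude": pf.amplitude, "frequency": pf.frequency, "hard": pf.hard}
        per_patient_counts_out[pid] = dict(counts)
        j = 0
        for cls, n in class_spec:
            for _ in range(n):
                trajectories.append(
                    simulate_trajectory(
                        params, cls, pf, rng=rng,
                        point_id=f"{pid}_pt{j:05d}", patient_id=pid,
                    )
                )
                j += 1

    manifest = CohortManifest(
        master_seed=int(seed),
        params=asdict(params),
        patient_ids=patient_ids,
        counts=per_patient_counts_out,
        factors=factors,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for pid in patient_ids:
            path = out_dir / f"{pid}.csv"
            write_trajectories([tr for tr in trajectories if tr.patient_id == pid], path)
            manifest.files[pid] = str(path)
        manifest.to_yaml(out_dir / "manifest.yaml")
    return manifest, trajectories


def load_cohort(manifest_path) -> tuple[CohortManifest, list[Trajectory]]:
    """Load a cohort written by :func:`simulate_cohort`."""
    manifest = CohortManifest.from_yaml(manifest_path)
    trajectories: list[Trajectory] = []
    for pid in manifest.patient_ids:
        path = Path(manifest.files[pid])
        if not path.exists():
            raise DataError(f"manifest references missing file {path}")
        trajectories.extend(read_trajectories(path))
    return manifest, trajectories
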