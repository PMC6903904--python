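"""Synthetic data generation for both arms of the flux pipeline.

Every input the analysis consumes can be generated here with known ground
truth: saturation-transfer ³¹P NMR datasets (control / γ-ATP-saturated /
mirror-saturated FIDs plus inversion-recovery series) and dynamic
¹³C glutamate mass-isotopomer timecourses from a [2-¹³C]acetate infusion.
Cohorts draw per-animal truths from group-level distributions so the full
pipeline — estimation, coupling index, group statistics — is testable end
to end without external data.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .isotopomer_model import (
    IsotopomerTimecourse,
    MetabolicNetwork,
    assemble_mass_isotopomer_odes,
    build_default_network,
    perturb_mass_isotopomer_distributions,
    simulate_labeling,
)
from .nmr_processing import FidRecord
from .saturation_transfer import RESONANCE_PPM, InversionRecoverySeries

__all__ = [
    "AcquisitionParams",
    "TruthRecord",
    "AcetateInput",
    "GroupParams",
    "STDataset",
    "AnimalData",
    "Cohort",
    "CONTROL_GROUP_PARAMS",
    "TUMOR_GROUP_PARAMS",
    "DEFAULT_INV_TIMES",
    "generate_fid",
    "generate_saturation_transfer_dataset",
    "acetate_input_function",
    "generate_labeling_dataset",
    "generate_cohort",
]

#: inversion-time range of the inversion-recovery acquisition (seconds)
DEFAULT_INV_TIMES = np.linspace(0.152, 7.651, 10)

#: natural linewidth (Hz) of the synthetic ³¹P resonances before apodization
_NATURAL_FWHM_HZ = 15.0


@dataclass
class AcquisitionParams:
    """Spectrometer acquisition settings for synthetic FIDs.

    Defaults describe a 9.4 T system: 161.98 MHz ³¹P frequency, 10 kHz
    sweep (dwell 0.1 ms), 4,000 complex points.  ``noise_sd`` is the
    standard deviation of the complex Gaussian noise per FID point, in
    the same units as peak amplitudes (concentration scale).
    """

    dwell_time: float = 1e-4
    n_points: int = 4000
    spectrometer_freq: float = 161.98
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points <= 0:
            raise ValueError("n_points must be positive")
        if self.dwell_time <= 0:
            raise ValueError("dwell_time must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class TruthRecord:
    """Ground-truth physiology for one synthetic animal.

    Concentrations in μmol/g wet weight, rate constants in 1/sec, fluxes
    in μmol/g/sec.  ``pool_sizes`` overrides metabolite pools of the
    labeling network.  The PCr → γ-ATP exchange (kf_pcr, T1_PCr) is
    carried so the same saturation-transfer machinery can analyze the
    PCr resonance.
    """

    kf_true: float = 0.04
    T1_Pi_true: float = 2.0
    Pi_conc: float = 2.1
    ATP_conc: float = 5.5
    PCr_conc: float = 20.0
    F_TCA_true: float = 0.018
    F_X_true: float = 0.06
    kf_pcr_true: float = 0.02
    T1_PCr_true: float = 3.0
    pool_sizes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "kf_true", "T1_Pi_true", "Pi_conc", "ATP_conc", "PCr_conc",
            "F_TCA_true", "F_X_true", "kf_pcr_true", "T1_PCr_true",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def atp_flux_true(self) -> float:
        return self.kf_true * self.Pi_conc


@dataclass
class AcetateInput:
    """Plasma [2-¹³C]acetate enrichment input function.

    A saturating exponential rise from ``baseline_enrichment`` to
    ``plateau_enrichment`` with rate ``rise_rate`` (1/sec) — the simplest
    monotone form for an infusion approaching steady state.  The infusion
    protocol of the original experiment is not specified; these defaults
    are placeholders chosen at physiological scale and should be replaced
    when protocol data are available.
    """

    baseline_enrichment: float = 0.0
    plateau_enrichment: float = 0.9
    rise_rate: float = 1.0 / 60.0
    plasma_conc: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline_enrichment <= self.plateau_enrichment <= 1.0:
            raise ValueError(
                "need 0 <= baseline_enrichment <= plateau_enrichment <= 1"
            )
        if self.rise_rate < 0:
            raise ValueError("rise_rate must be non-negative")

    def as_function(self):
        return lambda t: acetate_input_function(self, t)


def acetate_input_function(inp: AcetateInput, t) -> float | np.ndarray:
    """Plasma tracer enrichment at time ``t`` (seconds)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    rise = 1.0 - np.exp(-inp.rise_rate * t)
    value = inp.baseline_enrichment + (
        inp.plateau_enrichment - inp.baseline_enrichment
    ) * rise
    return float(value) if value.ndim == 0 else value


# ---------------------------------------------------------------------------
# NMR signal synthesis
# ---------------------------------------------------------------------------


def generate_fid(
    peaks: list[tuple[float, float, float, float]],
    acq: AcquisitionParams,
    rng: np.random.Generator | None = None,
) -> FidRecord:
    """Synthesize a complex FID as a sum of damped oscillations + noise.

    Each peak is ``(chemical_shift_ppm, amplitude, r2, gauss_fraction)``:
    an oscillation at shift·freq Hz with a Lorentzian envelope
    ``exp(−r2·t)`` (spectral FWHM r2/π) mixed, by ``gauss_fraction`` of
    the area, with a Gaussian envelope of matching FWHM.  Peak amplitude
    equals the spectral area, so areas are directly proportional to
    concentrations regardless of linewidth.
    """
    sw = 1.0 / acq.dwell_time
    t = np.arange(acq.n_points) * acq.dwell_time
    fid = np.zeros(acq.n_points, dtype=complex)
    for shift_ppm, amplitude, r2, gauss_fraction in peaks:
        freq = shift_ppm * acq.spectrometer_freq
        if not -sw / 2 < freq < sw / 2:
            raise ValueError(
                f"peak at {shift_ppm} ppm ({freq:.0f} Hz) outside spectral "
                f"width ±{sw / 2:.0f} Hz"
            )
        if r2 <= 0:
            raise ValueError("peak decay rate r2 must be positive")
        if not 0.0 <= gauss_fraction <= 1.0:
            raise ValueError("gauss_fraction must lie in [0, 1]")
        tau = np.sqrt(2.0 * np.log(2.0)) / r2  # Gaussian envelope matching FWHM
        envelope = (1.0 - gauss_fraction) * np.exp(-r2 * t) + gauss_fraction * np.exp(
            -(t**2) / (2.0 * tau**2)
        )
        fid += amplitude * envelope * np.exp(2j * np.pi * freq * t)
    if acq.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(acq.seed)
        noise = rng.normal(0.0, acq.noise_sd, (2, acq.n_points))
        fid += noise[0] + 1j * noise[1]
    return FidRecord(
        samples=fid,
        dwell_time=acq.dwell_time,
        spectrometer_freq=acq.spectrometer_freq,
        metadata={"n_points": acq.n_points, "noise_sd": acq.noise_sd},
    )


@dataclass
class STDataset:
    """One animal's saturation-transfer acquisition set."""

    control_fid: FidRecord
    saturated_fid: FidRecord
    mirror_fid: FidRecord
    ir: dict[str, InversionRecoverySeries]
    atp_conc: float
    truth: TruthRecord | None = None


def generate_saturation_transfer_dataset(
    truth: TruthRecord,
    acq: AcquisitionParams,
    inv_times: np.ndarray | None = None,
) -> STDataset:
    """Synthesize control, γ-ATP-saturated and mirror-saturated spectra
    plus inversion-recovery series for Pi and PCr.

    Peak amplitudes are proportional to concentrations.  Under γ-ATP
    saturation the Pi amplitude follows the two-site steady state
    1/(1 + kf·T1(Pi)) and the inversion-recovery series decays with
    1/T1app = 1/T1(Pi) + kf; PCr behaves likewise with its own exchange
    parameters.  The mirror acquisition (saturation mirrored about Pi,
    away from any resonance) reproduces the control amplitudes and is the
    M0 reference downstream.
    """
    if truth.T1_Pi_true <= 0 or truth.T1_PCr_true <= 0:
        raise ValueError("intrinsic T1 values must be positive")
    if inv_times is None:
        inv_times = DEFAULT_INV_TIMES
    inv_times = np.asarray(inv_times, dtype=float)
    if inv_times.size == 0:
        raise ValueError("inv_times must be non-empty")

    rng = np.random.default_rng(acq.seed)
    r2 = np.pi * _NATURAL_FWHM_HZ
    full_peaks = {
        "PCr": (RESONANCE_PPM["PCr"], truth.PCr_conc, r2, 0.0),
        "Pi": (RESONANCE_PPM["Pi"], truth.Pi_conc, r2, 0.0),
        "gATP": (RESONANCE_PPM["gATP"], truth.ATP_conc, r2, 0.0),
    }
    sat_pi = truth.Pi_conc / (1.0 + truth.kf_true * truth.T1_Pi_true)
    sat_pcr = truth.PCr_conc / (1.0 + truth.kf_pcr_true * truth.T1_PCr_true)
    saturated_peaks = {
        "PCr": (RESONANCE_PPM["PCr"], sat_pcr, r2, 0.0),
        "Pi": (RESONANCE_PPM["Pi"], sat_pi, r2, 0.0),
    }

    control = generate_fid(list(full_peaks.values()), acq, rng=rng)
    saturated = generate_fid(list(saturated_peaks.values()), acq, rng=rng)
    mirror = generate_fid(list(full_peaks.values()), acq, rng=rng)

    t1app_pi = 1.0 / (1.0 / truth.T1_Pi_true + truth.kf_true)
    t1app_pcr = 1.0 / (1.0 / truth.T1_PCr_true + truth.kf_pcr_true)
    ir = {}
    for label, a1, t1app in (
        ("Pi", sat_pi, t1app_pi),
        ("PCr", sat_pcr, t1app_pcr),
    ):
        y = a1 * (1.0 - 2.0 * np.exp(-inv_times / t1app))
        if acq.noise_sd > 0:
            y = y + rng.normal(0.0, acq.noise_sd, y.shape)
        ir[label] = InversionRecoverySeries(
            inv_times=inv_times, magnetization=y, resonance_label=label
        )
    return STDataset(
        control_fid=control,
        saturated_fid=saturated,
        mirror_fid=mirror,
        ir=ir,
        atp_conc=truth.ATP_conc,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# 13C labeling synthesis
# ---------------------------------------------------------------------------

#: default GC/MS sampling grid (seconds): 21 samples over a 15-minute
#: infusion window, dense enough to resolve the labeling transient that
#: carries the absolute flux information
DEFAULT_SAMPLE_TIMES = np.linspace(0.0, 900.0, 21)


def generate_labeling_dataset(
    network: MetabolicNetwork,
    truth: TruthRecord,
    inp: AcetateInput,
    sample_times: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    natural_abundance: float = 0.0,
) -> IsotopomerTimecourse:
    """Forward-simulate glutamate labeling at the truth fluxes and sample
    it with measurement noise.

    ``natural_abundance`` optionally folds a baseline ¹³C fraction
    (1.07% in nature) into every input carbon and the initial state;
    off by default.

    Independent Gaussian noise of SD ``noise_sd`` (fraction units) is
    added to every mass-isotopomer fraction, truncated to [0, 1], and
    each distribution renormalized to sum 1 — the standard GC/MS error
    model.  ``noise_sd=0`` returns the simulation output exactly.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if sample_times is None:
        sample_times = DEFAULT_SAMPLE_TIMES
    sample_times = np.asarray(sample_times, dtype=float)
    if sample_times.size < 3 or np.any(np.diff(sample_times) <= 0):
        raise ValueError("sample_times must be increasing with >= 3 points")

    system = assemble_mass_isotopomer_odes(network)
    tc = simulate_labeling(
        system,
        fluxes={"F_TCA": truth.F_TCA_true, "F_X": truth.F_X_true},
        pools=truth.pool_sizes or None,
        input_fn=inp.as_function(),
        t_grid=sample_times,
        natural_abundance=natural_abundance,
    )
    if noise_sd == 0.0:
        return tc
    rng = np.random.default_rng(seed)
    return perturb_mass_isotopomer_distributions(tc, noise_sd, rng)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass
class GroupParams:
    """Group-level means ± standard errors with group sizes.

    Per-animal truths are drawn as Gaussians with SD = SE·√n (the
    between-animal spread implied by a reported standard error),
    truncated at zero by redraw.
    """

    atp_flux_mean: float = 0.084
    atp_flux_se: float = 0.009
    atp_n: int = 10
    tca_flux_mean: float = 0.018
    tca_flux_se: float = 0.005
    tca_n: int = 18
    fx_mean: float = 0.06

    def atp_flux_sd(self) -> float:
        return self.atp_flux_se * np.sqrt(self.atp_n)

    def tca_flux_sd(self) -> float:
        return self.tca_flux_se * np.sqrt(self.tca_n)


#: group parameters for the control and tumor-bearing arms
CONTROL_GROUP_PARAMS = GroupParams(0.084, 0.009, 10, 0.018, 0.005, 18, 0.06)
TUMOR_GROUP_PARAMS = GroupParams(0.043, 0.013, 6, 0.014, 0.003, 18, 0.06)


@dataclass
class AnimalData:
    animal_id: str
    group: str
    truth: TruthRecord
    st: STDataset | None = None
    labeling: IsotopomerTimecourse | None = None
    labeling_noise_sd: float = 0.0


@dataclass
class Cohort:
    animals: list[AnimalData]

    def truth_table(self) -> pd.DataFrame:
        rows = [
            {
                "animal_id": a.animal_id,
                "group": a.group,
                "atp_flux_true": a.truth.atp_flux_true,
                "kf_true": a.truth.kf_true,
                "tca_flux_true": a.truth.F_TCA_true,
                "fx_true": a.truth.F_X_true,
            }
            for a in self.animals
        ]
        return pd.DataFrame(rows)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0:
        return mean
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > 0:
            return v
    raise RuntimeError("truncated-normal draw failed; check mean/SD signs")


def generate_cohort(
    n_C: int,
    n_TB: int,
    group_params: dict[str, GroupParams] | None = None,
    seed: int = 0,
    modalities: tuple[str, ...] = ("st", "labeling"),
    acq: AcquisitionParams | None = None,
    base_truth: TruthRecord | None = None,
    network: MetabolicNetwork | None = None,
    acetate: AcetateInput | None = None,
    sample_times: np.ndarray | None = None,
    labeling_noise_sd: float = 0.02,
    inv_times: np.ndarray | None = None,
) -> Cohort:
    """Generate a two-group cohort with per-animal ground truth.

    Per-animal ATP synthesis flux and TCA flux are drawn from the group
    distributions (mean, SD = SE·√n, truncated at 0); kf is derived from
    the drawn ATP flux at the configured [Pi].  The same seed always
    reproduces the identical cohort.
    """
    if n_C < 1 or n_TB < 1:
        raise ValueError("both groups need at least one animal")
    if group_params is None:
        group_params = {"C": CONTROL_GROUP_PARAMS, "TB": TUMOR_GROUP_PARAMS}
    if acq is None:
        acq = AcquisitionParams()
    if base_truth is None:
        base_truth = TruthRecord()
    if acetate is None:
        acetate = AcetateInput()
    if "labeling" in modalities and network is None:
        network = build_default_network()

    master = np.random.SeedSequence(seed)
    animals: list[AnimalData] = []
    specs = [("C", i, group_params["C"]) for i in range(n_C)] + [
        ("TB", i, group_params["TB"]) for i in range(n_TB)
    ]
    children = master.spawn(len(specs))
    for (group, i, gp), child in zip(specs, children):
        rng = np.random.default_rng(child)
        atp_flux = _truncated_normal(rng, gp.atp_flux_mean, gp.atp_flux_sd())
        tca_flux = _truncated_normal(rng, gp.tca_flux_mean, gp.tca_flux_sd())
        truth = replace(
            base_truth,
            kf_true=atp_flux / base_truth.Pi_conc,
            F_TCA_true=tca_flux,
            F_X_true=gp.fx_mean,
        )
        animal = AnimalData(animal_id=f"{group}{i + 1:02d}", group=group, truth=truth)
        sub_seed = int(child.generate_state(1)[0] % 2**31)
        if "st" in modalities:
            animal.st = generate_saturation_transfer_dataset(
                truth,
                replace(acq, seed=sub_seed),
                inv_times=inv_times,
            )
        if "labeling" in modalities:
            animal.labeling = generate_labeling_dataset(
                network,
                truth,
                acetate,
                sample_times=sample_times,
                noise_sd=labeling_noise_sd,
                seed=sub_seed + 1,
            )
            animal.labeling_noise_sd = labeling_noise_sd
        animals.append(animal)
    return Cohort(animals=animals)
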