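"""Synthetic chromatogram generator.

Emulates the two peak classes the classifiers must separate, with the
statistical structure of real Skyline exports:

* peptide groups — three co-eluting Gaussian isotope traces scaled by a
  tryptic-like isotope envelope, small mass error, idotP near 1;
* noise groups — one of three failure morphologies per group: a low-S/N
  jagged trace, a peak integrated outside its true elution window, or
  isotope traces with discordant shapes and injected elution lags. Noise
  idotP is drawn around a median of 0.90, so a substantial fraction of
  noise passes the conventional idotP >= 0.85 annotation filter — the very
  premise that motivates classifier-based assignment.

Each noise group carries a single dominant defect, so no single feature
separates the classes on its own while the joint distribution does.
A quantification generator produces light/heavy dimethyl pairs for
equal-mix (or spiked-ratio) experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._domain import AnnotatedExample, IsotopeTrace, PrecursorPeakGroup
from .features import extract_features

__all__ = [
    "SimSpec",
    "NOISE_MORPHOLOGIES",
    "simulate_peak_group",
    "simulate_dataset",
    "simulate_quant_experiment",
]

NOISE_MORPHOLOGIES = ("low_snr", "offset_window", "discordant")


@dataclass
class SimSpec:
    """Parameters of the simulated world.

    Defaults model a nanoLC gradient sampled every 3 s (0.05 min) with peak
    widths sigma of 0.05-0.15 min, a 0.6/0.3/0.1 M/M+1/M+2 envelope, and the
    class structure described above. Each noise group draws a defect severity
    ``s = u ** (1/separation)`` with ``u ~ U(0, 1)``: at ``separation`` 1
    severities are uniform (substantial class overlap, as in manually
    annotated data); larger values push severities toward 1 and make the
    classes cleanly separable. 1.0 is the realistic default.
    """

    n_peptide: int = 380
    n_noise: int = 357
    seed: int = 0
    separation: float = 1.0
    sampling_interval: float = 0.05  # minutes
    sigma_range: tuple[float, float] = (0.05, 0.15)  # minutes
    isotope_envelope: tuple[float, float, float] = (0.6, 0.3, 0.1)
    jitter: float = 0.04  # peptide multiplicative intensity jitter
    noise_jitter: float = 0.5  # jaggedness of low-S/N noise traces
    lag_range: tuple[int, int] = (1, 5)  # injected lags, samples
    baseline: float = 0.02  # baseline level relative to apex
    dropout: float = 0.1  # chance a noise group loses an isotope trace
    apex_log10_range: tuple[float, float] = (4.0, 7.0)
    peptide_idotp: tuple[float, float] = (0.97, 0.02)  # mean, sd
    noise_idotp: tuple[float, float] = (0.90, 0.08)  # median 0.90 by construction
    peptide_ppm_sd: float = 1.5
    noise_ppm_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.n_peptide < 0 or self.n_noise < 0:
            raise ValueError("counts must be non-negative")
        env = np.asarray(self.isotope_envelope, dtype=float)
        if np.any(env < 0) or abs(env.sum() - 1.0) > 1e-9:
            raise ValueError("isotope_envelope entries must be >= 0 and sum to 1")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")


def _gaussian(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _grid(center: float, sigma: float, spec: SimSpec) -> np.ndarray:
    half = 5.0 * sigma
    n = max(int(round(2 * half / spec.sampling_interval)) + 1, 7)
    return center - half + spec.sampling_interval * np.arange(n)


def _peptide_traces(
    spec: SimSpec, rng: np.random.Generator
) -> tuple[list[IsotopeTrace], dict[int, float]]:
    sigma = rng.uniform(*spec.sigma_range)
    center = rng.uniform(5.0, 25.0)
    apex = 10.0 ** rng.uniform(*spec.apex_log10_range)
    t = _grid(center, sigma, spec)
    b_lo, b_hi = center - 2.5 * sigma, center + 2.5 * sigma
    jit = spec.jitter
    traces, areas = [], {}
    for i, frac in enumerate(spec.isotope_envelope):
        shape = frac * apex * _gaussian(t, center, sigma)
        y = shape * (1.0 + jit * rng.standard_normal(t.size))
        y += spec.baseline * frac * apex * rng.random(t.size)
        y = np.clip(y, 0.0, None)
        traces.append(IsotopeTrace(i, t, y, b_lo, b_hi))
        areas[i] = float(np.trapezoid(y[(t >= b_lo) & (t <= b_hi)], dx=spec.sampling_interval))
    return traces, areas


def _noise_traces(
    spec: SimSpec, rng: np.random.Generator, morphology: str, severity: float
) -> tuple[list[IsotopeTrace], dict[int, float]]:
    """One noise group: a peptide-like peak degraded by a single defect.

    ``severity`` in [0, 1] scales the defect; near 0 the group is almost
    indistinguishable from a peptide (the irreducible class overlap seen in
    manually annotated noise), near 1 the defect is blatant.
    """
    sigma = rng.uniform(*spec.sigma_range)
    center = rng.uniform(5.0, 25.0)
    apex = 10.0 ** rng.uniform(*spec.apex_log10_range)
    t = _grid(center, sigma, spec)
    n_traces = 3 if rng.random() > spec.dropout else 2
    jit = spec.jitter

    traces: list[IsotopeTrace] = []
    if morphology == "low_snr":
        # signal sinks toward the baseline and grows jagged
        amp = apex * 10.0 ** (-1.5 * severity)
        rel_noise = jit + severity * spec.noise_jitter
        b_lo, b_hi = center - 2.5 * sigma, center + 2.5 * sigma
        for i in range(n_traces):
            frac = spec.isotope_envelope[i]
            shape = frac * amp * _gaussian(t, center, sigma)
            y = shape * (1.0 + rel_noise * rng.standard_normal(t.size))
            y += spec.baseline * frac * apex * rng.random(t.size)
            traces.append(IsotopeTrace(i, t, np.clip(y, 0.0, None), b_lo, b_hi))
    elif morphology == "offset_window":
        # clean co-eluting peak integrated off its apex
        offset = (0.5 + 3.0 * severity) * sigma
        b_lo = min(center + offset, t[-1] - 2 * spec.sampling_interval)
        b_hi = min(b_lo + 3.0 * sigma, t[-1])
        for i, frac in enumerate(spec.isotope_envelope[:n_traces]):
            shape = frac * apex * _gaussian(t, center, sigma)
            y = shape * (1.0 + jit * rng.standard_normal(t.size))
            y += spec.baseline * frac * apex * rng.random(t.size)
            traces.append(IsotopeTrace(i, t, np.clip(y, 0.0, None), b_lo, b_hi))
    elif morphology == "discordant":
        # isotope shapes and elution times disagree; M+1 always lags >= 1 sample
        b_lo, b_hi = center - 2.5 * sigma, center + 2.5 * sigma
        lo, hi = spec.lag_range
        for i, frac in enumerate(spec.isotope_envelope[:n_traces]):
            if i == 0:
                lag = 0
                sig_i = sigma
            else:
                base_lag = rng.uniform(lo, hi) * severity
                lag = max(lo, round(base_lag)) if i == 1 else round(base_lag)
                lag *= 1 if rng.random() < 0.5 else -1
                sig_i = sigma * 2.0 ** rng.uniform(-0.3 - severity, 0.3 + severity)
            shape = frac * apex * _gaussian(t, center + lag * spec.sampling_interval, sig_i)
            y = shape * (1.0 + jit * rng.standard_normal(t.size))
            y += spec.baseline * frac * apex * rng.random(t.size)
            traces.append(IsotopeTrace(i, t, np.clip(y, 0.0, None), b_lo, b_hi))
    else:
        raise ValueError(f"unknown noise morphology: {morphology!r}")

    areas = {
        tr.isotope_index: float(
            np.trapezoid(tr.window()[1], dx=spec.sampling_interval)
        )
        for tr in traces
    }
    return traces, areas


def simulate_peak_group(
    kind: str,
    spec: SimSpec,
    rng: np.random.Generator,
    *,
    morphology: str | None = None,
    sequence: str = "SIMPEPTIDEK",
    charge: int = 2,
    label_type: str = "none",
) -> tuple[PrecursorPeakGroup, str]:
    """Draw one peak group of the given kind ('peptide' or 'noise').

    Noise groups take one of the three failure morphologies (chosen
    uniformly unless ``morphology`` is given). Returns the group and its
    annotation label.
    """
    if kind == "peptide":
        traces, areas = _peptide_traces(spec, rng)
        mu, sd = spec.peptide_idotp
        idotp = float(np.clip(rng.normal(mu, sd), 0.0, 1.0))
        ppm = float(rng.normal(0.0, spec.peptide_ppm_sd))
    elif kind == "noise":
        morph = morphology or NOISE_MORPHOLOGIES[rng.integers(0, len(NOISE_MORPHOLOGIES))]
        # defect severity: uniform at separation 1; higher separation pushes
        # severities toward 1, lower toward 0 (monotone in separation)
        severity = float(rng.random() ** (1.0 / max(spec.separation, 1e-6)))
        traces, areas = _noise_traces(spec, rng, morph, severity)
        mu, sd = spec.noise_idotp
        idotp = float(np.clip(rng.normal(mu, sd), 0.0, 1.0))
        ppm = float(rng.normal(0.0, spec.noise_ppm_sd))
    else:
        raise ValueError(f"kind must be 'peptide' or 'noise', got {kind!r}")

    group = PrecursorPeakGroup(
        modified_sequence=sequence,
        charge=charge,
        label_type=label_type,
        traces=traces,
        idotp=idotp,
        mass_error_ppm=ppm,
        areas=areas,
        retention_time=float(np.mean([tr.boundary_start for tr in traces])),
    )
    return group, kind


def simulate_dataset(
    spec: SimSpec,
) -> tuple[list[AnnotatedExample], list[PrecursorPeakGroup]]:
    """Generate ``n_peptide + n_noise`` annotated groups and their features.

    Reproducible for a fixed ``spec.seed``; each group consumes its own
    child random stream, so the draw for one group does not perturb others.
    """
    total = spec.n_peptide + spec.n_noise
    if total < 1:
        raise ValueError("n_peptide + n_noise must be >= 1")
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(spec.seed).spawn(total)]
    examples: list[AnnotatedExample] = []
    groups: list[PrecursorPeakGroup] = []
    kinds = ["peptide"] * spec.n_peptide + ["noise"] * spec.n_noise
    for i, (kind, rng) in enumerate(zip(kinds, streams)):
        group, label = simulate_peak_group(
            kind, spec, rng, sequence=f"SIM{i:04d}K", charge=2 + i % 3
        )
        groups.append(group)
        examples.append(
            AnnotatedExample(
                features=extract_features(group), annotation=label, source_id=f"sim{i:04d}"
            )
        )
    return examples, groups


def simulate_quant_experiment(
    n_pairs: int,
    true_log_ratio: float = 0.0,
    noise_sd: float = 0.2,
    seed: int = 0,
    *,
    n_distorted: int = 0,
    distortion_sd: float = 1.5,
    spec: SimSpec | None = None,
) -> list[PrecursorPeakGroup]:
    """Light/heavy dimethyl pairs from a mixing experiment.

    Heavy areas follow ``light * 2**(-(true_log_ratio + eps))`` with
    ``eps ~ N(0, noise_sd)`` on the log2 scale, so ``true_log_ratio = 0``
    emulates an equal mix. ``n_distorted`` of the pairs are built from noise
    morphologies with idotP/mass error forced through the conventional
    filter and a much larger ratio distortion — the pollution the unanimous
    vote is meant to reject.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not (0 <= n_distorted <= n_pairs):
        raise ValueError("n_distorted must lie in [0, n_pairs]")
    spec = spec or SimSpec()
    env = np.asarray(spec.isotope_envelope)
    streams = np.random.SeedSequence(seed).spawn(n_pairs)
    groups: list[PrecursorPeakGroup] = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        distorted = i < n_distorted
        base_seq = f"QPEP{i:04d}K"
        sides = {}
        for label, tag in (("light", "[+28]"), ("heavy", "[+34]")):
            kind = "noise" if distorted else "peptide"
            g, _ = simulate_peak_group(
                kind, spec, rng, sequence=base_seq + tag, charge=2, label_type=label
            )
            if distorted:
                # slips past idotP / mass-error thresholds by construction
                g.idotp = float(rng.uniform(0.9, 1.0))
                g.mass_error_ppm = float(rng.uniform(-6.0, 6.0))
            sides[label] = g
        light_total = 10.0 ** rng.uniform(5.0, 8.0)
        sd = distortion_sd if distorted else noise_sd
        eps = rng.normal(0.0, sd) if sd > 0 else 0.0
        heavy_total = light_total * 2.0 ** (-(true_log_ratio + eps))
        sides["light"].areas = {k: float(light_total * env[k]) for k in range(3)}
        sides["heavy"].areas = {k: float(heavy_total * env[k]) for k in range(3)}
        groups.extend([sides["light"], sides["heavy"]])
    return groups
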