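"""Ground-truthed LC-MS run simulator.

Emulates the signal structure the method reasons about: Gaussian elution
profiles sampled on a regular MS1 grid, natural-13C isotope envelopes on
both channels, binomial incomplete-15N-labeling envelopes on the heavy
channel, ppm-scale mass error, multiplicative intensity noise, and
data-dependent top-k MS2 selection with dynamic exclusion.  Every emitted
species is recorded in a truth manifest so detection, classification,
pairing, identification and quantification can all be scored against known
ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from .constants import (
    C13_ABUNDANCE,
    CARBAMIDOMETHYL_CARBONS,
    DELTA_13C,
    DELTA_15N,
    PROTON_MASS,
    RESIDUE_CARBONS,
)
from .peptide_db import DigestParams, monoisotopic_mass, nitrogen_count
from .spectra_io import MS1Spectrum, MS2Spectrum, Run
from .msms_search import theoretical_fragments

#: Residues used to build random tryptic peptides (no K/R/P internally).
_BODY_RESIDUES = "ACDEFGHILMNQSTVWY"


def carbon_count(sequence: str, fixed_mods: bool = True) -> int:
    """Carbon atoms of a peptide, counting carbamidomethyl carbons."""
    n = sum(RESIDUE_CARBONS[aa] for aa in sequence)
    if fixed_mods:
        n += CARBAMIDOMETHYL_CARBONS * sequence.count("C")
    return n


def labeling_envelope(
    n_nitrogens: int, enrichment: float, truncate: float = 1e-4
) -> dict[int, float]:
    """Relative abundance by number of *unlabeled* nitrogens ``k``.

    Binomial law: each of the N nitrogens is 15N with probability equal to
    the enrichment ``e``; weight(k) = C(N,k) e^(N-k) (1-e)^k.  Weights
    below ``truncate`` of the maximum are dropped and the rest
    renormalized.
    """
    if n_nitrogens < 1:
        raise ValueError("need at least one nitrogen")
    if not (0 < enrichment <= 1):
        raise ValueError("enrichment must lie in (0, 1]")
    ks = np.arange(n_nitrogens + 1)
    w = _sstats.binom.pmf(ks, n_nitrogens, 1.0 - enrichment)
    keep = w >= truncate * w.max()
    w = w[keep] / w[keep].sum()
    return {int(k): float(x) for k, x in zip(ks[keep], w)}


def carbon_envelope(n_carbons: int, truncate: float = 1e-4) -> dict[int, float]:
    """Relative abundance by 13C count under natural abundance 0.0107."""
    if n_carbons < 1:
        raise ValueError("need at least one carbon")
    ks = np.arange(n_carbons + 1)
    w = _sstats.binom.pmf(ks, n_carbons, C13_ABUNDANCE)
    keep = w >= truncate * w.max()
    w = w[keep] / w[keep].sum()
    return {int(k): float(x) for k, x in zip(ks[keep], w)}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated run.

    Defaults describe a desk-scale analog of a high-resolution metabolic
    labeling experiment: 50 random proteins of 6 clean tryptic peptides
    each, 0.98 15N enrichment, 1 ppm mass error, a 15-minute gradient
    sampled every 0.03 min, and top-7 data-dependent MS2 with dynamic
    exclusion.
    """

    seed: int
    n_proteins: int = 50
    peptides_per_protein: int = 6
    peptide_len: tuple[int, int] = (7, 13)
    max_peptide_mass: float = 1450.0
    proteome: list[tuple[str, str]] | None = None
    true_log2_ratios: dict[str, float] | None = None
    ratio_log2_sd: float = 1.5
    enrichment: float = 0.98
    mass_error_ppm_sd: float = 1.0
    intensity_noise_cv: float = 0.1
    elution_sd_min: float = 0.08
    gradient_min: float = 15.0
    ms1_interval_min: float = 0.03
    ms2_top_k: int = 7
    ms2_exclusion_min: float = 0.3
    ms2_min_intensity: float = 200.0
    ms2_noise_peaks: int = 10
    ms2_fragment_keep: float = 1.0  # fraction of ladder peaks retained
    base_intensity_range: tuple[float, float] = (4.2, 5.3)  # log10 apex
    min_emitted_intensity: float = 2.0
    envelope_truncate: float = 1e-4
    rt_offset_heavy_min: float = 0.0
    swap_labels: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.enrichment <= 1):
            raise ValueError("enrichment must lie in (0, 1]")
        if self.mass_error_ppm_sd < 0 or self.intensity_noise_cv < 0:
            raise ValueError("noise levels must be >= 0")


def random_proteome(config: SimConfig, rng: np.random.Generator) -> list[tuple[str, str]]:
    """Random proteins made of clean tryptic peptides.

    Each peptide is a run of non-K/R/P residues terminated by K or R, so
    the digest recovers exactly the designed peptides; masses are capped
    to keep every species within the charge-2/3 regime of the instrument
    model.
    """
    seen: set[str] = set()
    proteome = []
    for i in range(config.n_proteins):
        peptides = []
        while len(peptides) < config.peptides_per_protein:
            length = int(rng.integers(config.peptide_len[0], config.peptide_len[1] + 1))
            body = "".join(rng.choice(list(_BODY_RESIDUES), size=length - 1))
            pep = body + ("K" if rng.random() < 0.5 else "R")
            if pep in seen:
                continue
            if monoisotopic_mass(pep) > config.max_peptide_mass:
                continue
            seen.add(pep)
            peptides.append(pep)
        proteome.append((f"SIMPROT{i:03d}", "".join(peptides)))
    return proteome


@dataclass(frozen=True)
class _Species:
    """One isotopologue of one channel of one peptide."""

    peptide: str
    protein: str
    channel: str  # "light" | "heavy"
    charge: int
    n_unlabeled: int  # 15N deficit k (heavy channel only)
    n_c13: int
    mz: float
    weight: float  # within-channel relative abundance
    is_mono: bool


def _peptide_species(
    pep: str,
    protein: str,
    charge: int,
    enrichment: float,
    truncate: float,
) -> list[_Species]:
    mass_l = monoisotopic_mass(pep, labeled=False)
    n_n = nitrogen_count(pep)
    mass_h = mass_l + n_n * DELTA_15N
    n_c = carbon_count(pep)
    cenv = carbon_envelope(n_c, truncate)
    lenv = labeling_envelope(n_n, enrichment, truncate)
    species: list[_Species] = []
    for k, cw in cenv.items():
        species.append(
            _Species(
                pep, protein, "light", charge, 0, k,
                (mass_l + k * DELTA_13C) / charge + PROTON_MASS,
                cw, is_mono=(k == 0),
            )
        )
    # Heavy channel: labeling deficit x carbon envelope.  Weights are
    # normalized to the fully labeled (j=0) species so the configured
    # channel ratio is carried by the monoisotopic pair the method
    # measures; the incomplete-labeling satellites sit on top of it.
    weights = {
        (j, k): (lw / lenv[0]) * cw for j, lw in lenv.items() for k, cw in cenv.items()
    }
    wmax = max(weights.values())
    weights = {jk: w for jk, w in weights.items() if w >= truncate * wmax}
    for (j, k), w in sorted(weights.items()):
        species.append(
            _Species(
                pep, protein, "heavy", charge, j, k,
                (mass_h - j * DELTA_15N + k * DELTA_13C) / charge + PROTON_MASS,
                w, is_mono=(j == 0 and k == 0),
            )
        )
    return species


def simulate_run(config: SimConfig) -> tuple[Run, pd.DataFrame, pd.DataFrame]:
    """Simulate one LC-MS run.

    Returns ``(run, peptide_truth, species_truth)``: the in-memory run plus
    a per-peptide manifest (channel m/z values, areas, true log2 ratio,
    MS2 scan ids) and a per-species table mapping every emitted
    isotopologue trace to its theoretical m/z, channel area and
    monoisotopic flag.
    """
    rng = np.random.default_rng(config.seed)
    proteome = config.proteome or random_proteome(config, rng)

    digest = DigestParams()
    peptides: list[tuple[str, str]] = []
    seen: set[str] = set()
    for acc, seq in proteome:
        for pep in _split_clean_peptides(seq, digest):
            if pep not in seen:
                seen.add(pep)
                peptides.append((pep, acc))
    if not peptides:
        raise ValueError("proteome digests to no usable peptides")

    ratios = dict(config.true_log2_ratios or {})
    for acc, _ in proteome:
        if acc not in ratios:
            ratios[acc] = float(rng.normal(0.0, config.ratio_log2_sd))

    rt_lo, rt_hi = 1.0, config.gradient_min - 1.0
    times = np.arange(0.0, config.gradient_min, config.ms1_interval_min)
    n_scans = len(times)

    all_species: list[_Species] = []
    pep_rows = []
    pep_meta: dict[str, dict] = {}
    for pep, acc in peptides:
        mass = monoisotopic_mass(pep)
        charge = 2 if mass < 1250.0 else 3
        rt_center = float(rng.uniform(rt_lo, rt_hi))
        apex = 10.0 ** rng.uniform(*config.base_intensity_range)
        r = ratios[acc]
        # orientation: heavy/light = 2**r; a label swap negates r
        r_eff = -r if config.swap_labels else r
        heavy_scale = 2.0 ** r_eff
        sp = _peptide_species(
            pep, acc, charge, config.enrichment, config.envelope_truncate
        )
        all_species.extend(sp)
        pep_meta[pep] = {
            "rt_center": rt_center,
            "apex": apex,
            "heavy_scale": heavy_scale,
            "protein": acc,
            "true_log2": r,
        }

    # emit Gaussian traces per species
    sigma = config.elution_sd_min
    norm = sigma * math.sqrt(2.0 * math.pi)
    scan_peaks_mz: list[list[float]] = [[] for _ in range(n_scans)]
    scan_peaks_int: list[list[float]] = [[] for _ in range(n_scans)]
    # per (species index, scan) emitted intensity for DDA selection
    emitted: list[dict[int, float]] = [dict() for _ in range(n_scans)]
    species_rows = []
    log_noise_sd = math.sqrt(math.log1p(config.intensity_noise_cv**2))

    for si, sp in enumerate(all_species):
        meta = pep_meta[sp.peptide]
        rt0 = meta["rt_center"] + (
            config.rt_offset_heavy_min if sp.channel == "heavy" else 0.0
        )
        scale = meta["heavy_scale"] if sp.channel == "heavy" else 1.0
        apex = meta["apex"] * scale * sp.weight
        lo = int(np.searchsorted(times, rt0 - 3.5 * sigma))
        hi = int(np.searchsorted(times, rt0 + 3.5 * sigma))
        window = times[lo:hi]
        if len(window) == 0:
            continue
        profile = apex * np.exp(-0.5 * ((window - rt0) / sigma) ** 2)
        if config.intensity_noise_cv > 0:
            profile = profile * rng.lognormal(
                -0.5 * log_noise_sd**2, log_noise_sd, size=len(window)
            )
        ppm = (
            rng.normal(0.0, config.mass_error_ppm_sd, size=len(window))
            if config.mass_error_ppm_sd > 0
            else np.zeros(len(window))
        )
        kept = profile >= config.min_emitted_intensity
        area = float(np.trapezoid(profile[kept], window[kept])) if kept.sum() > 1 else 0.0
        for off, (t_i, inten, e) in enumerate(zip(window, profile, ppm)):
            if inten < config.min_emitted_intensity:
                continue
            s = lo + off
            scan_peaks_mz[s].append(sp.mz * (1.0 + e * 1e-6))
            scan_peaks_int[s].append(float(inten))
            emitted[s][si] = float(inten)
        species_rows.append(
            {
                "peptide": sp.peptide,
                "protein": sp.protein,
                "channel": sp.channel,
                "charge": sp.charge,
                "n_unlabeled": sp.n_unlabeled,
                "n_c13": sp.n_c13,
                "mz": sp.mz,
                "weight": sp.weight,
                "is_mono": sp.is_mono,
                "area": area,
                "rt_center": rt0,
            }
        )

    ms1 = [
        MS1Spectrum(
            scan_id=s + 1,
            retention_time=float(times[s]),
            mz=np.array(scan_peaks_mz[s]),
            intensity=np.array(scan_peaks_int[s]),
        )
        for s in range(n_scans)
    ]

    # data-dependent MS2: top-k species per cycle with dynamic exclusion
    ms2: list[MS2Spectrum] = []
    last_selected: dict[int, float] = {}
    ms2_of_pep: dict[tuple[str, str], list[int]] = {}
    scan_counter = n_scans
    for s in range(n_scans):
        t = float(times[s])
        ranked = sorted(emitted[s].items(), key=lambda kv: (-kv[1], kv[0]))
        picked = 0
        for si, inten in ranked:
            if picked >= config.ms2_top_k:
                break
            if inten < config.ms2_min_intensity:
                break
            if t - last_selected.get(si, -math.inf) < config.ms2_exclusion_min:
                continue
            sp = all_species[si]
            last_selected[si] = t
            picked += 1
            scan_counter += 1
            label = "labeled" if sp.channel == "heavy" else "unlabeled"
            frags = theoretical_fragments(sp.peptide, label, sp.charge)
            if config.ms2_fragment_keep < 1.0:
                keep = rng.random(len(frags)) < config.ms2_fragment_keep
                if keep.sum() < 2:
                    keep[:2] = True
                frags = frags[keep]
            f_int = rng.uniform(100.0, 1000.0, size=len(frags))
            noise_mz = rng.uniform(150.0, 1500.0, size=config.ms2_noise_peaks)
            noise_int = rng.uniform(2.0, 60.0, size=config.ms2_noise_peaks)
            ms2.append(
                MS2Spectrum(
                    scan_id=scan_counter,
                    retention_time=t + config.ms1_interval_min * 0.25,
                    precursor_mz=sp.mz * (1.0 + rng.normal(0, config.mass_error_ppm_sd) * 1e-6),
                    precursor_charge=sp.charge,
                    mz=np.concatenate([frags, noise_mz]),
                    intensity=np.concatenate([f_int, noise_int]),
                )
            )
            ms2_of_pep.setdefault((sp.peptide, sp.channel), []).append(scan_counter)

    species_truth = pd.DataFrame(species_rows)
    for pep, acc in peptides:
        meta = pep_meta[pep]
        mine = species_truth[species_truth["peptide"] == pep]
        area_l = float(mine.loc[mine["channel"] == "light", "area"].sum())
        area_h = float(mine.loc[mine["channel"] == "heavy", "area"].sum())
        mono = mine[mine["is_mono"]]
        pep_rows.append(
            {
                "peptide": pep,
                "protein": acc,
                "charge": int(mine["charge"].iloc[0]),
                "nitrogen_count": nitrogen_count(pep),
                "mz_light": float(mono.loc[mono["channel"] == "light", "mz"].iloc[0]),
                "mz_heavy": float(mono.loc[mono["channel"] == "heavy", "mz"].iloc[0]),
                "area_light": area_l,
                "area_heavy": area_h,
                "true_log2_ratio": meta["true_log2"],
                "rt_center": meta["rt_center"],
                "ms2_scans": ";".join(
                    map(str, ms2_of_pep.get((pep, "light"), []) +
                        ms2_of_pep.get((pep, "heavy"), []))
                ),
            }
        )
    peptide_truth = pd.DataFrame(pep_rows)
    run = Run(ms1=ms1, ms2=ms2, metadata={"simulated": True, "seed": config.seed})
    return run, peptide_truth, species_truth


def _split_clean_peptides(seq: str, params: DigestParams) -> list[str]:
    """Zero-missed-cleavage digest used to recover the designed peptides."""
    import re

    frags = [f for f in re.split(params.cleave_pattern, seq) if f]
    return [f for f in frags if params.min_len <= len(f) <= params.max_len]
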