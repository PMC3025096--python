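"""Ground-truthed synthetic two-condition LC-MS phosphoproteomics data.

Emulates the study design the rest of the package analyses: IMAC-enriched
tryptic phosphopeptides from one normal and one cataractous lens, separated
over a 120-min gradient and observed as centroided MS1 features in the
instrument's m/z 400-1600 acceptance window. Each phosphopeptide elutes as a
Gaussian chromatographic peak whose amplitude in the case condition is the
control amplitude times a known true fold-ratio; case runs suffer a linear
retention-time distortion plus segment-wise offsets; point intensities carry
multiplicative noise; identifications drop out stochastically (the
data-dependent acquisition lottery); and PSM scores are drawn from separate
true-match and false-match score populations with decoy labels.

Everything emitted is traceable to a :class:`GroundTruthLedger`, which is the
oracle for recovery tests: true ratios, true per-run apex times, true
modification sites, PSM truth labels and the distortion parameters per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import masscalc
from .fdr import PSM, PSMTable
from .masscalc import ModifiedPeptide, PHOSPHO
from .quant import FeatureMap

AMINO_ACIDS = "".join(sorted(masscalc.MONOISOTOPIC_RESIDUE_MASS))


@dataclass
class SimulationConfig:
    """Study conditions for the simulator; the seed is mandatory."""

    seed: int
    n_proteins: int = 20
    protein_length: tuple[int, int] = (150, 400)
    n_peptides: int = 50
    peptide_length: tuple[int, int] = (7, 25)
    charge_probs: tuple[float, float] = (0.6, 0.4)      # P(2+), P(3+)
    gradient: tuple[float, float] = (0.0, 120.0)        # min
    rt_margin: float = 5.0                               # keep peaks inside the gradient
    mz_range: tuple[float, float] = (400.0, 1600.0)     # instrument acceptance, Th
    min_mz_separation: float = 0.12                      # Th, avoid XIC cross-talk
    peak_sigma: float = 0.1                              # min
    sampling_interval: float = 0.01                      # min (~80 points per peak)
    log_intensity_mean: float = 11.5                     # ln of control peak amplitude
    log_intensity_sd: float = 0.5
    ratio_range: tuple[float, float] = (0.25, 4.0)       # true ratios, log-uniform
    n_control_runs: int = 1
    n_case_runs: int = 1
    rt_slope: float = 1.02                               # case-run linear distortion
    rt_intercept: float = -0.5                           # min
    rt_bumps: tuple[tuple[float, float, float], ...] = ((40.0, 60.0, 0.4),)
    noise_cv: float = 0.10                               # per-point multiplicative CV
    id_rt_jitter: float = 0.02                           # min, identification RT error
    dropout: float = 0.10                                # P(peptide not identified in a run)
    score_true: tuple[float, float] = (60.0, 12.0)       # true-match score mean/sd
    score_false: tuple[float, float] = (25.0, 8.0)       # false-match score mean/sd
    false_psm_fraction: float = 0.5                      # false matches per true match
    decoy_fraction: float = 0.5                          # share of false matches on decoys

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for p in (*self.charge_probs, self.dropout, self.decoy_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.gradient[0] >= self.gradient[1]:
            raise ValueError("degenerate gradient span")
        if self.mz_range[0] >= self.mz_range[1]:
            raise ValueError("degenerate m/z range")


@dataclass
class GroundTruthLedger:
    """The oracle behind a simulated experiment."""

    peptides: pd.DataFrame      # key, accession, sequence, phospho_pos, charge, mz,
                                # base_rt, amplitude, true_ratio
    rt_per_run: pd.DataFrame    # key, run_id, condition, apex_rt
    psm_labels: pd.DataFrame    # peptide, score, is_decoy, is_true
    distortions: dict[str, tuple[float, float, tuple]]  # run -> (slope, intercept, bumps)

    def true_ratio(self, key: str) -> float:
        return float(self.peptides.set_index("key").loc[key, "true_ratio"])

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.peptides.to_csv(directory / "ledger_peptides.tsv", sep="\t", index=False)
        self.rt_per_run.to_csv(directory / "ledger_rt.tsv", sep="\t", index=False)
        self.psm_labels.to_csv(directory / "ledger_psms.tsv", sep="\t", index=False)


@dataclass
class SimulatedExperiment:
    feature_maps: list[FeatureMap]
    identifications: pd.DataFrame   # run_id, condition, key, sequence, charge, rt, mz, score
    psms: PSMTable
    ledger: GroundTruthLedger

    def write(self, directory) -> None:
        """Write the TSV schemas the pipeline consumes."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.concat([m.to_frame() for m in self.feature_maps]).to_csv(
            directory / "features.tsv", sep="\t", index=False)
        self.identifications.to_csv(directory / "identifications.tsv", sep="\t", index=False)
        self.psms.to_frame().to_csv(directory / "psms.tsv", sep="\t", index=False)
        self.ledger.write(directory)


def random_proteome(rng: np.random.Generator, config: SimulationConfig) -> dict[str, str]:
    """Uniform-composition random protein sequences."""
    proteins = {}
    lo, hi = config.protein_length
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
        proteins[f"SYN{i:04d}"] = seq
    return proteins


def _draw_phosphopeptides(rng: np.random.Generator, config: SimulationConfig,
                          proteins: dict[str, str]) -> pd.DataFrame:
    """Tryptic phosphopeptide candidates: digest, pick a phosphosite and charge,
    keep those inside the m/z acceptance window with distinct m/z."""
    candidates = []
    for acc, seq in proteins.items():
        for frag in masscalc.tryptic_digest(seq, max_missed_cleavages=0):
            if not config.peptide_length[0] <= len(frag.sequence) <= config.peptide_length[1]:
                continue
            sty = [i + 1 for i, aa in enumerate(frag.sequence) if aa in "STY"]
            if sty:
                candidates.append((acc, frag, sty))
    rng.shuffle(candidates)
    chosen, used_mz, used_seq = [], [], set()
    for acc, frag, sty in candidates:
        if len(chosen) >= config.n_peptides:
            break
        if frag.sequence in used_seq:
            continue
        pos = int(rng.choice(sty))
        charge = 2 if rng.random() < config.charge_probs[0] else 3
        peptide = ModifiedPeptide(frag.sequence, ((pos, PHOSPHO),), charge)
        mz = masscalc.compute_mz(masscalc.peptide_monoisotopic_mass(peptide), charge)
        if not config.mz_range[0] <= mz <= config.mz_range[1]:
            continue
        if any(abs(mz - u) < config.min_mz_separation for u in used_mz):
            continue
        chosen.append({"key": peptide.key, "accession": acc,
                       "sequence": frag.sequence, "phospho_pos": pos,
                       "charge": charge, "mz": mz,
                       "designation": masscalc.annotate_site_position(frag, pos)})
        used_mz.append(mz)
        used_seq.add(frag.sequence)
    if not chosen:
        raise ValueError("configuration produced zero phosphopeptides")
    return pd.DataFrame(chosen)


def _distort(t: float, slope: float, intercept: float,
             bumps: Sequence[tuple[float, float, float]]) -> float:
    out = slope * t + intercept
    for start, end, offset in bumps:
        if start <= t < end:
            out += offset
    return out


def simulate_psm_scores(n_true: int, n_false: int, config: SimulationConfig,
                        rng: Optional[np.random.Generator] = None
                        ) -> tuple[PSMTable, pd.DataFrame]:
    """PSM scores from the true-match and false-match populations.

    True matches are always targets; false matches land on decoys with
    probability ``decoy_fraction`` and on targets otherwise (the separate
    decoy-search symmetry assumption). Returns the table and its truth labels.
    """
    if n_true < 0 or n_false < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    psms, labels = [], []
    mu_t, sd_t = config.score_true
    mu_f, sd_f = config.score_false
    for i in range(n_true):
        score = float(rng.normal(mu_t, sd_t))
        psms.append(PSM(f"TRUE{i:05d}", score, is_decoy=False))
        labels.append({"peptide": f"TRUE{i:05d}", "score": score,
                       "is_decoy": False, "is_true": True})
    for i in range(n_false):
        score = float(rng.normal(mu_f, sd_f))
        is_decoy = bool(rng.random() < config.decoy_fraction)
        psms.append(PSM(f"FALSE{i:05d}", score, is_decoy=is_decoy))
        labels.append({"peptide": f"FALSE{i:05d}", "score": score,
                       "is_decoy": is_decoy, "is_true": False})
    return PSMTable(psms), pd.DataFrame(labels)


def simulate_experiment(config: SimulationConfig,
                        proteins: Optional[dict[str, str]] = None) -> SimulatedExperiment:
    """Generate a complete two-condition experiment with its ground truth."""
    rng = np.random.default_rng(config.seed)
    if proteins is None:
        proteins = random_proteome(rng, config)
    peptides = _draw_phosphopeptides(rng, config, proteins)
    n = len(peptides)

    lo, hi = config.gradient
    peptides["base_rt"] = rng.uniform(lo + config.rt_margin, hi - config.rt_margin, size=n)
    peptides["amplitude"] = np.exp(rng.normal(config.log_intensity_mean,
                                              config.log_intensity_sd, size=n))
    r_lo, r_hi = config.ratio_range
    if r_lo == r_hi:
        peptides["true_ratio"] = float(r_lo)
    else:
        peptides["true_ratio"] = np.exp(rng.uniform(np.log(r_lo), np.log(r_hi), size=n))

    runs = ([("normal", f"normal_{i+1}") for i in range(config.n_control_runs)]
            + [("cataract", f"cataract_{i+1}") for i in range(config.n_case_runs)])
    distortions = {}
    for condition, run_id in runs:
        if condition == "cataract":
            distortions[run_id] = (config.rt_slope, config.rt_intercept, config.rt_bumps)
        else:
            distortions[run_id] = (1.0, 0.0, ())

    # multiplicative log-normal point noise with unit mean and the target CV
    cv = config.noise_cv
    log_sd = float(np.sqrt(np.log(1.0 + cv * cv))) if cv > 0 else 0.0

    feature_maps, rt_rows, id_rows = [], [], []
    sigma = config.peak_sigma
    for condition, run_id in runs:
        slope, intercept, bumps = distortions[run_id]
        pts = []
        for pep in peptides.itertuples(index=False):
            apex = _distort(pep.base_rt, slope, intercept, bumps)
            amp = pep.amplitude * (pep.true_ratio if condition == "cataract" else 1.0)
            offsets = np.arange(-4 * sigma, 4 * sigma + config.sampling_interval / 2,
                                config.sampling_interval)
            times = apex + offsets
            keep = (times >= lo) & (times <= hi)
            times = times[keep]
            shape = amp * np.exp(-0.5 * ((times - apex) / sigma) ** 2)
            if log_sd > 0:
                shape = shape * np.exp(rng.normal(-0.5 * log_sd ** 2, log_sd, size=len(times)))
            pts.append(pd.DataFrame({"mz": pep.mz, "rt": times, "intensity": shape,
                                     "key": pep.key}))
            rt_rows.append({"key": pep.key, "run_id": run_id,
                            "condition": condition, "apex_rt": apex})
            if rng.random() >= config.dropout:
                id_rt = apex + (rng.normal(0.0, config.id_rt_jitter)
                                if config.id_rt_jitter > 0 else 0.0)
                id_rows.append({"run_id": run_id, "condition": condition,
                                "key": pep.key, "sequence": pep.sequence,
                                "charge": pep.charge, "rt": float(id_rt),
                                "mz": pep.mz})
        feature_maps.append(FeatureMap(run_id, condition, pd.concat(pts, ignore_index=True),
                                       gradient=config.gradient))

    identifications = pd.DataFrame(
        id_rows, columns=["run_id", "condition", "key", "sequence", "charge", "rt", "mz"])
    n_true = len(identifications)
    n_false = int(round(config.false_psm_fraction * n_true))
    psms, psm_labels = simulate_psm_scores(n_true, n_false, config, rng)
    # attach the true-match scores to the identifications, in order
    identifications["score"] = [p.score for p in psms.psms[:n_true]]

    ledger = GroundTruthLedger(
        peptides=peptides,
        rt_per_run=pd.DataFrame(rt_rows),
        psm_labels=psm_labels,
        distortions=distortions,
    )
    return SimulatedExperiment(feature_maps, identifications, psms, ledger)
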