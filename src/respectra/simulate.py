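"""Ground-truth generators: rule-based fragmentation, noisy spectrum rendering,
decoys, PSM benchmarks with known labels, and spliced/canonical confusion pairs.

The fragmentation rule is deliberately simple but encodes three real
phenomena of HCD spectra so that model-recovery experiments are meaningful:

* enhanced cleavage N-terminal to proline (the y ion at a Xaa-Pro bond is
  boosted),
* charge/intensity retention by basic residues (b ions lacking K/R/H are
  suppressed when the complementary y ion carries them; fragment charge
  states follow the basic-residue count),
* a collision-energy tilt that moves intensity toward low-mass fragments as
  NCE rises.

Every generator is a pure function of (config, seed): reruns are
bit-identical.  In the noiseless limit the renderer and the annotator are
exact inverses, which is the keystone oracle for annotation and training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import (FragmentMatrix, IONS, N_CHARGES, base_peak_normalize,
                       mask_array, theoretical_ions)
from .chem import (BASIC_RESIDUES, ISOBARIC_SUBSTITUTIONS, PROTON, Peptide,
                   RESIDUE_MASS, fragment_neutral_mass, peptide_mass)
from .io import PSMRecord, RawSpectrum

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: peptide length ranges per set type; AspN/LysN carry D/K at the N-terminus
PRESETS = {
    "hla1": {"lengths": (8, 12), "nterm": None},
    "hla2": {"lengths": (10, 25), "nterm": None},
    "aspn": {"lengths": (7, 25), "nterm": "D"},
    "lysn": {"lengths": (7, 25), "nterm": "K"},
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic surface.

    Defaults emulate a well-behaved Orbitrap HCD acquisition: 5 ppm mass
    jitter, one unannotated noise peak per 100 Th, log-normal intensity
    scatter sigma 0.3, HLA class I length range, NCE 30, charge mix
    dominated by 2+.
    """

    seed: int = 0
    preset: str = "hla1"
    nce: float = 30.0
    ppm_jitter: float = 5.0
    noise_per_100th: float = 1.0
    intensity_sigma: float = 0.3
    charge_probs: tuple[float, ...] = (0.15, 0.60, 0.25)  # z = 1, 2, 3
    rawfile: str = "synthetic_run"

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def has_fragment_collisions(peptide: Peptide, tol_ppm: float = 25.0) -> bool:
    """True if any two theoretical b/y ions fall within each other's
    matching windows (such peptides cannot be annotated back exactly from a
    rendered spectrum because coincident peaks merge physically)."""
    mzs = sorted(mz for _, _, _, mz in theoretical_ions(peptide))
    return any(b - a <= 2.5 * tol_ppm * 1e-6 * b for a, b in zip(mzs, mzs[1:]))


def sample_peptides(n: int, cfg: SimConfig, rng: np.random.Generator | None = None,
                    collision_free: bool = False) -> list[Peptide]:
    """Draw ``n`` peptides with unique sequences from the preset distribution."""
    rng = cfg.rng() if rng is None else rng
    preset = PRESETS[cfg.preset]
    lo, hi = preset["lengths"]
    charges = np.arange(1, len(cfg.charge_probs) + 1)
    probs = np.asarray(cfg.charge_probs) / sum(cfg.charge_probs)
    seen: set[str] = set()
    out: list[Peptide] = []
    while len(out) < n:
        length = int(rng.integers(lo, hi + 1))
        letters = rng.choice(list(ALPHABET), size=length)
        if preset["nterm"] is not None:
            letters[0] = preset["nterm"]
        seq = "".join(letters)
        if seq in seen:
            continue
        seen.add(seq)
        peptide = Peptide(seq, (), int(rng.choice(charges, p=probs)))
        if collision_free and has_fragment_collisions(peptide):
            continue
        out.append(peptide)
    return out


def simulate_fragmentation(peptide: Peptide, nce: float = 30.0) -> FragmentMatrix:
    """Deterministic ground-truth fragment intensities for one peptide.

    For cleavage site i (1-based, between residues i and i+1) of a length-L
    peptide, the site propensity is a centred Gaussian
    ``s_i = exp(-(i - L/2)^2 / (2 (L/4)^2))``, tripled when residue i+1 is
    proline.  y ions start at twice the b intensity; the b ion is further
    scaled by 0.3 when it contains no basic residue but its complementary y
    does.  Fragment charge k <= min(3, precursor charge) is weighted
    ``exp(-|k - (1 + n_basic/2)|)`` with n_basic counted in the fragment, and
    each intensity is tilted by ``(m_frag/m_prec)^(-0.5 (nce - 30)/10)``.
    The result is base-peak normalized with masked entries at -1.
    """
    seq = peptide.sequence
    L = len(seq)
    matrix = FragmentMatrix.zeros(L, peptide.precursor_charge)
    prec_mass = peptide_mass(peptide)
    kmax = min(N_CHARGES, peptide.precursor_charge)
    for site in range(1, L):
        propensity = math.exp(-((site - L / 2) ** 2) / (2 * (L / 4) ** 2))
        if seq[site] == "P":  # cleavage N-terminal to proline
            propensity *= 3.0
        b_seq, y_seq = seq[:site], seq[site:]
        b_base, y_base = propensity, 2.0 * propensity
        b_basic = sum(ch in BASIC_RESIDUES for ch in b_seq)
        y_basic = sum(ch in BASIC_RESIDUES for ch in y_seq)
        if b_basic == 0 and y_basic > 0:
            b_base *= 0.3
        for ion_idx, (frag_pos, base, n_basic) in enumerate(
            ((site, b_base, b_basic), (L - site, y_base, y_basic))
        ):
            m_frag = fragment_neutral_mass(peptide, IONS[ion_idx], frag_pos)
            tilt = (m_frag / prec_mass) ** (-0.5 * (nce - 30.0) / 10.0)
            weights = np.array([math.exp(-abs(k - (1 + n_basic / 2)))
                                for k in range(1, kmax + 1)])
            weights /= weights.sum()
            for k in range(1, kmax + 1):
                matrix.values[frag_pos - 1, ion_idx, k - 1] = base * tilt * weights[k - 1]
    return base_peak_normalize(matrix)


class RuleBasedIntensityPredictor:
    """The generator exposed through the predictor interface.

    Serves as the exact oracle in round-trip tests and as the prediction
    source for collision-energy calibration experiments.
    """

    def predict_matrix(self, peptide: Peptide, nce: float) -> FragmentMatrix:
        return simulate_fragmentation(peptide, nce)

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        out = np.empty((len(frame), 174))
        for i, row in enumerate(frame.itertuples(index=False)):
            peptide = Peptide.from_modified_sequence(
                row.modified_sequence, precursor_charge=int(row.precursor_charge))
            out[i] = simulate_fragmentation(peptide, float(row.nce)).flat
        return out


def render_spectrum(matrix: FragmentMatrix, peptide: Peptide, cfg: SimConfig,
                    rng: np.random.Generator, scan: int = 1) -> RawSpectrum:
    """Render a peak list: ppm jitter, log-normal intensity scatter, noise peaks."""
    mzs: list[float] = []
    intensities: list[float] = []
    for pos, ion_idx, charge, mz in theoretical_ions(peptide):
        value = matrix.values[pos - 1, ion_idx, charge - 1]
        if value <= 0:
            continue
        eps = rng.normal(0.0, cfg.ppm_jitter * 1e-6) if cfg.ppm_jitter > 0 else 0.0
        scatter = rng.lognormal(0.0, cfg.intensity_sigma) if cfg.intensity_sigma > 0 else 1.0
        mzs.append(mz * (1.0 + eps))
        intensities.append(value * scatter)
    if mzs:
        lo, hi = 100.0, max(mzs) * 1.05
    else:
        lo, hi = 100.0, 1500.0
    if cfg.noise_per_100th > 0:
        n_noise = rng.poisson(cfg.noise_per_100th * (hi - lo) / 100.0)
        for _ in range(n_noise):
            mzs.append(rng.uniform(lo, hi))
            intensities.append(rng.uniform(0.0, 0.5))
    z = peptide.precursor_charge
    return RawSpectrum(
        mz=np.asarray(mzs), intensity=np.asarray(intensities),
        precursor_mz=(peptide_mass(peptide) + z * PROTON) / z,
        precursor_charge=z, nce=cfg.nce, analyzer="FTMS",
        scan=scan, rawfile=cfg.rawfile,
    )


def generate_decoy(peptide: Peptide) -> Peptide:
    """Full sequence reversal (non-tryptic: no C-terminal anchor to keep).

    Palindromic sequences are perturbed by one internal swap so the decoy
    differs from the target.  Modifications follow their residues.
    """
    seq = peptide.sequence
    rev = seq[::-1]
    if rev == seq:
        chars = list(rev)
        chars[1], chars[2] = chars[2], chars[1]
        rev = "".join(chars)
        mods = ()  # positions no longer track cleanly for the rare palindrome
    else:
        n = len(seq)
        mods = tuple((n - pos + 1, mod) for pos, mod in peptide.modifications)
    return Peptide(rev, mods, peptide.precursor_charge)


@dataclass
class SyntheticPSM:
    """One generated PSM with its spectrum and, for targets, the truth tensor."""

    psm: PSMRecord
    spectrum: RawSpectrum
    truth: FragmentMatrix | None


def generate_dataset(n_targets: int, cfg: SimConfig, n_decoys: int = 0,
                     score_effect: float = 3.0) -> list[SyntheticPSM]:
    """Targets with truth-rendered spectra plus reversed-sequence decoy PSMs.

    Decoy PSMs reuse target spectra (a decoy is a wrong explanation of a
    real spectrum); engine scores are Gaussian with a ``score_effect`` shift
    for targets.
    """
    rng = cfg.rng()
    peptides = sample_peptides(n_targets, cfg, rng)
    out: list[SyntheticPSM] = []
    for scan, peptide in enumerate(peptides, start=1):
        truth = simulate_fragmentation(peptide, cfg.nce)
        spectrum = render_spectrum(truth, peptide, cfg, rng, scan=scan)
        psm = PSMRecord(cfg.rawfile, scan, peptide, engine="synthetic",
                        engine_score=float(rng.normal(score_effect, 1.0)),
                        is_decoy=False, retention_time=float(rng.uniform(5, 60)))
        out.append(SyntheticPSM(psm, spectrum, truth))
    for i in range(n_decoys):
        source = out[int(rng.integers(0, n_targets))]
        decoy = generate_decoy(source.psm.peptide)
        psm = PSMRecord(cfg.rawfile, source.psm.scan, decoy, engine="synthetic",
                        engine_score=float(rng.normal(0.0, 1.0)), is_decoy=True,
                        retention_time=source.psm.retention_time)
        out.append(SyntheticPSM(psm, source.spectrum, None))
    return out


def training_frame(peptides: list[Peptide], nce: float) -> tuple[pd.DataFrame, np.ndarray]:
    """(metadata frame, masked 174-d target matrix) for predictor training."""
    frame = pd.DataFrame({
        "modified_sequence": [p.modified_sequence for p in peptides],
        "precursor_charge": [p.precursor_charge for p in peptides],
        "nce": nce,
    })
    targets = np.stack([simulate_fragmentation(p, nce).flat for p in peptides])
    return frame, targets


@dataclass
class ConfusionPair:
    """A proposed spliced peptide, its canonical competitor, and the spectrum
    (rendered from the canonical truth)."""

    spliced_sequence: str           # contains the splice-position marker '|'
    canonical: Peptide
    spliced: Peptide
    spectrum: RawSpectrum
    substitution: tuple[str, str]


def generate_confusion_pairs(n: int, cfg: SimConfig | None = None,
                             seed: int | None = None) -> list[ConfusionPair]:
    """Isobaric spliced/canonical pairs (GVA<->NL, GG<->N, GA<->Q, I<->L).

    The canonical sequence embeds the right-hand motif; the spliced proposal
    replaces it with the isobaric left-hand motif, marking the splice
    junction with ``|``.  Spectra are rendered from the canonical truth so
    downstream re-assessment runs against known ground truth.
    """
    if cfg is None:
        cfg = SimConfig(seed=seed if seed is not None else 0)
    rng = cfg.rng()
    pairs: list[ConfusionPair] = []
    seen: set[str] = set()
    while len(pairs) < n:
        spliced_motif, canonical_motif = ISOBARIC_SUBSTITUTIONS[
            int(rng.integers(0, len(ISOBARIC_SUBSTITUTIONS)))]
        core = max(8, 10 - len(canonical_motif))
        prefix_len = int(rng.integers(3, core - 1))
        suffix_len = core - prefix_len
        prefix = "".join(rng.choice(list(ALPHABET), size=prefix_len))
        suffix = "".join(rng.choice(list(ALPHABET), size=suffix_len))
        canonical_seq = prefix + canonical_motif + suffix
        spliced_seq = prefix + spliced_motif + suffix
        if canonical_seq in seen or canonical_seq == spliced_seq:
            continue
        seen.add(canonical_seq)
        charge = int(rng.choice([1, 2, 2, 3]))
        canonical = Peptide(canonical_seq, (), charge)
        spliced = Peptide(spliced_seq, (), charge)
        truth = simulate_fragmentation(canonical, cfg.nce)
        spectrum = render_spectrum(truth, canonical, cfg, rng, scan=len(pairs) + 1)
        pairs.append(ConfusionPair(
            spliced_sequence=f"{prefix}|{spliced_motif}{suffix}",
            canonical=canonical, spliced=spliced, spectrum=spectrum,
            substitution=(spliced_motif, canonical_motif),
        ))
    return pairs


BENCHMARK_FEATURES = ("spectral_angle", "pearson", "frac_pred_matched", "delta_score")
_BENCHMARK_WEIGHTS = np.array([1.0, 0.8, 0.6, 0.4])


def generate_psm_benchmark(n_true: int, n_false: int, n_decoy: int,
                           effect_size: float, seed: int) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Labeled PSM benchmark for FDR-calibration experiments.

    True targets get a mean shift of ``effect_size`` times per-feature
    weights; false targets and decoys are drawn from the identical standard
    normal (exchangeability), so the observed false-discovery proportion is
    computable exactly.  Returns (features, is_decoy, is_true).
    """
    rng = np.random.default_rng(seed)
    n = n_true + n_false + n_decoy
    X = rng.normal(0.0, 1.0, size=(n, len(BENCHMARK_FEATURES)))
    X[:n_true] += effect_size * _BENCHMARK_WEIGHTS
    is_decoy = np.zeros(n, dtype=bool)
    is_decoy[n_true + n_false:] = True
    is_true = np.zeros(n, dtype=bool)
    is_true[:n_true] = True
    order = rng.permutation(n)
    frame = pd.DataFrame(X[order], columns=BENCHMARK_FEATURES)
    frame.index = pd.RangeIndex(n)
    return frame, is_decoy[order], is_true[order]


def sample_from_pwm(pwm, n: int, seed: int | np.random.Generator = 0) -> list[str]:
    """i.i.d. positional sampling of ``n`` sequences from a position-weight matrix."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    letters = np.array(list(pwm.alphabet))
    cols = [rng.choice(letters, size=n, p=pwm.matrix[:, j] / pwm.matrix[:, j].sum())
            for j in range(pwm.length)]
    return ["".join(row) for row in zip(*cols)]
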