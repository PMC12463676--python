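"""Seeded synthetic-data generators for every pipeline stage.

Each generator is a pure function of its parameters and a seed, drawing
from an independent random stream keyed by (seed, generator-name), and
returns a ground-truth record alongside the data so recovery can be
checked without external downloads.

What the generators emulate (and what they do not) is documented in the
package's methods note; defaults follow the shapes of the corresponding
real experiments (10-temperature TPP grid, 384-well plates, half-log dose
series, multi-predictor disorder tracks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import derive_rng
from .idr import AMINO_ACIDS, DisorderProfile
from .imaging import FieldImage
from .screen import four_param_logistic
from .tpp import MeltCurveMatrix

__all__ = [
    "TPP_TEMPERATURES",
    "TppSimSpec",
    "melt_fraction",
    "gen_tpp",
    "gen_field_image",
    "gen_plate",
    "gen_dose_response",
    "gen_disorder",
    "synthetic_sfpq",
    "synthetic_srsf1",
]

#: The canonical 10-point TPP temperature gradient (deg C).
TPP_TEMPERATURES = np.array([37.0, 40.4, 44.0, 46.9, 49.8, 52.9, 55.5, 58.6, 62.0, 66.3])

# Average amino-acid frequencies of reviewed human-like proteomes, used for
# synthetic protein sequences.
_AA_FREQS = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}


def melt_fraction(t, tm, slope: float = 2.0, plateau: float = 0.05):
    """Soluble fraction at temperature ``t`` for melting point ``tm``.

    Standard two-state melt sigmoid with a non-melting plateau:
    f(T) = (1 - plateau) / (1 + exp((T - Tm)/slope)) + plateau.
    """
    t = np.asarray(t, dtype=float)
    return (1.0 - plateau) / (1.0 + np.exp((t - tm) / slope)) + plateau


@dataclass
class TppSimSpec:
    """Parameters of a synthetic TPP experiment.

    By default: proteins on the canonical 10-temperature grid, two
    conditions (vehicle control and one treatment), melting points uniform
    in 45-55 deg C, slope 2 deg C, plateau 0.05, multiplicative log-normal
    noise.  ``n_stabilized``/``n_destabilized`` proteins receive +/-
    ``delta_tm`` in the treatment arm; ``n_abundance`` receive a log2
    abundance shift ``delta_abundance`` (disjoint subsets).
    """

    n_proteins: int = 1000
    temperatures: np.ndarray = field(default_factory=lambda: TPP_TEMPERATURES.copy())
    conditions: tuple = ("DMSO", "treatment")
    control: str = "DMSO"
    tm_range: tuple = (45.0, 55.0)
    slope: float = 2.0
    plateau: float = 0.05
    n_stabilized: int = 0
    n_destabilized: int = 0
    n_abundance: int = 0
    delta_tm: float = 2.0
    delta_abundance: float = 1.0
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.plateau < 1:
            raise ValueError("plateau must be in [0, 1)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.n_stabilized + self.n_destabilized + self.n_abundance > self.n_proteins:
            raise ValueError("effect subsets exceed protein count")


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=shape))


def gen_tpp(spec: TppSimSpec) -> tuple[MeltCurveMatrix, pd.DataFrame]:
    """Simulate a melting-curve matrix plus per-protein ground truth.

    Affected proteins get their treatment-arm melting point shifted by
    ``delta_tm`` (positive for the stabilized subset, negative for the
    destabilized one) and/or their treatment-arm baseline multiplied by
    ``2**delta_abundance``.
    """
    rng = derive_rng(spec.seed, "tpp")
    n, temps = spec.n_proteins, spec.temperatures
    pids = [f"P{i:05d}" for i in range(n)]
    tm = rng.uniform(*spec.tm_range, size=n)
    baseline = rng.lognormal(np.log(1e6), 0.5, size=n)

    d_tm = np.zeros(n)
    d_ab = np.zeros(n)
    idx = rng.permutation(n)
    stab = idx[: spec.n_stabilized]
    destab = idx[spec.n_stabilized : spec.n_stabilized + spec.n_destabilized]
    abund = idx[
        spec.n_stabilized + spec.n_destabilized :
        spec.n_stabilized + spec.n_destabilized + spec.n_abundance
    ]
    d_tm[stab] = spec.delta_tm
    d_tm[destab] = -spec.delta_tm
    d_ab[abund] = spec.delta_abundance

    n_cond = len(spec.conditions)
    intensity = np.empty((n, len(temps), n_cond))
    for k, cond in enumerate(spec.conditions):
        treated = cond != spec.control
        tm_k = tm + (d_tm if treated else 0.0)
        amp_k = baseline * (2.0 ** d_ab if treated else 1.0)
        clean = amp_k[:, None] * melt_fraction(temps[None, :], tm_k[:, None],
                                               spec.slope, spec.plateau)
        intensity[:, :, k] = clean * _lognormal_noise(rng, spec.noise_cv, clean.shape)

    truth_class = np.full(n, "unaffected", dtype=object)
    truth_class[stab] = "stabilized"
    truth_class[destab] = "destabilized"
    truth = pd.DataFrame(
        {
            "protein_id": pids,
            "tm": tm,
            "delta_tm": d_tm,
            "delta_abundance": d_ab,
            "class": truth_class,
        }
    ).set_index("protein_id")
    matrix = MeltCurveMatrix(pids, temps, list(spec.conditions), intensity,
                             control=spec.control)
    return matrix, truth


def _place_points(rng, n, shape, margin, min_dist, max_tries=20000, inside=None):
    pts = []
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(f"could not place {n} points after {max_tries} tries")
        y = rng.uniform(margin, shape[0] - margin)
        x = rng.uniform(margin, shape[1] - margin)
        if inside is not None and not inside(y, x):
            continue
        if all((y - py) ** 2 + (x - px) ** 2 >= min_dist**2 for py, px in pts):
            pts.append((y, x))
    return np.array(pts).reshape(-1, 2)


def _blob(shape, centers, sigma, amplitude):
    img = np.zeros(shape)
    if len(centers) == 0:
        return img
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for (cy, cx) in centers:
        img += amplitude * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)))
    return img


def gen_field_image(
    n_nuclei: int = 10,
    granules_per_cell: float = 3.0,
    intranuclear_puncta: int = 0,
    shape: tuple = (512, 512),
    nucleus_sigma: float = 9.0,
    punctum_sigma: float = 1.6,
    nucleus_amplitude: float = 1000.0,
    punctum_amplitude: float = 800.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[FieldImage, dict]:
    """Render a two-channel field with known nucleus and punctum coordinates.

    Nuclei are broad Gaussian blobs in the DNA channel; the reporter channel
    carries a dim nuclear component plus bright cytoplasmic puncta (and,
    optionally, intranuclear puncta that a correct granule detector must
    exclude).  Additive Gaussian noise of SD ``noise_sd``; truth lists all
    coordinates.
    """
    if shape[0] < 64 or shape[1] < 64:
        raise ValueError("field must be at least 64x64")
    rng = derive_rng(seed, "field-image")
    margin = 4 * nucleus_sigma
    nuc = _place_points(rng, n_nuclei, shape, margin, min_dist=9 * nucleus_sigma)

    def far_from_nuclei(y, x):
        return all((y - cy) ** 2 + (x - cx) ** 2 >= (4.5 * nucleus_sigma) ** 2
                   for cy, cx in nuc)

    n_gran = int(round(n_nuclei * granules_per_cell))
    gran = _place_points(rng, n_gran, shape, 8, min_dist=10 * punctum_sigma,
                         inside=far_from_nuclei if n_nuclei else None)
    intra = []
    if intranuclear_puncta:
        if n_nuclei == 0:
            raise ValueError("cannot place intranuclear puncta without nuclei")
        for _ in range(intranuclear_puncta):
            cy, cx = nuc[rng.integers(0, n_nuclei)]
            intra.append((cy + rng.uniform(-1, 1), cx + rng.uniform(-1, 1)))
    intra = np.array(intra).reshape(-1, 2)

    dna = _blob(shape, nuc, nucleus_sigma, nucleus_amplitude)
    reporter = (
        0.25 * nucleus_amplitude / 1000.0 * _blob(shape, nuc, nucleus_sigma, 1000.0)
        + _blob(shape, gran, punctum_sigma, punctum_amplitude)
        + _blob(shape, intra, punctum_sigma, punctum_amplitude)
    )
    if noise_sd > 0:
        dna = np.clip(dna + rng.normal(0, noise_sd, shape), 0, None)
        reporter = np.clip(reporter + rng.normal(0, noise_sd, shape), 0, None)
    truth = {
        "nuclei": nuc,
        "granules": gran,
        "intranuclear": intra,
        "n_nuclei": n_nuclei,
        "n_granules": n_gran,
    }
    return FieldImage({"dna": dna, "reporter": reporter}, field_id="synthetic"), truth


def gen_plate(
    n_wells: int = 384,
    n_controls: int = 32,
    n_features: int = 15,
    hits: list | None = None,
    covariance: np.ndarray | None = None,
    plate_id: str = "plate_1",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one screening plate of multivariate-normal well features.

    Control and untreated wells draw from N(0, Sigma); each (well_index,
    shift_vector) in ``hits`` adds the shift (in feature SD units) to that
    treatment well.  Returns (well table in the screen-model layout, truth).
    """
    rng = derive_rng(seed, f"plate-{plate_id}")
    if covariance is None:
        # mildly correlated features, as granularity/texture features are
        a = rng.normal(0, 0.3, size=(n_features, n_features))
        covariance = np.eye(n_features) + a @ a.T / n_features
    x = rng.multivariate_normal(np.zeros(n_features), covariance, size=n_wells,
                                method="cholesky")
    roles = np.array(["treatment"] * n_wells, dtype=object)
    hit_idx = [w for w, _ in (hits or [])]
    if len(set(hit_idx)) != len(hit_idx):
        raise ValueError("duplicate hit wells")
    eligible = np.setdiff1d(np.arange(n_wells), np.array(hit_idx, dtype=int))
    if len(eligible) < n_controls:
        raise ValueError("not enough non-hit wells to host the controls")
    ctrl_idx = rng.choice(eligible, size=n_controls, replace=False)
    roles[ctrl_idx] = "control"
    hit_flags = np.zeros(n_wells, dtype=bool)
    sd = np.sqrt(np.diag(covariance))
    for well_idx, shift in (hits or []):
        x[well_idx] += np.asarray(shift) * sd
        hit_flags[well_idx] = True
    table = pd.DataFrame(x, columns=[f"feat_{j}" for j in range(n_features)])
    table.insert(0, "plate_id", plate_id)
    table.insert(1, "well_id", [f"{plate_id}:W{i:04d}" for i in range(n_wells)])
    table.insert(2, "compound_id", [f"cpd_{i:04d}" for i in range(n_wells)])
    table.insert(3, "role", roles)
    truth = pd.DataFrame(
        {"well_id": table["well_id"], "is_hit": hit_flags, "role": roles}
    ).set_index("well_id")
    return table, truth


def gen_dose_response(
    ec50: float = 2e-6,
    slope: float = 1.5,
    bottom: float = 0.2,
    top: float = 3.0,
    concentrations: np.ndarray | None = None,
    noise_cv: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate 4PL dose-response series (concentration in M).

    Default grid: 12 half-log points from 1 nM to ~316 uM.  Multiplicative
    log-normal noise with coefficient of variation ``noise_cv``.
    """
    if concentrations is None:
        concentrations = 10.0 ** np.arange(-9, -3, 0.5)
    rng = derive_rng(seed, "dose-response")
    conc = np.tile(np.asarray(concentrations, dtype=float), n_replicates)
    clean = four_param_logistic(conc, bottom, top, ec50, slope)
    resp = clean * _lognormal_noise(rng, noise_cv, clean.shape)
    curve = pd.DataFrame({"concentration": conc, "response": resp}).sort_values(
        "concentration", kind="stable", ignore_index=True
    )
    truth = {"ec50": ec50, "slope": slope, "bottom": bottom, "top": top}
    return curve, truth


# Disorder-biased residue pools: IDRs deplete hydrophobics and enrich
# polar/charged residues; the "stabilized" class additionally enriches R/Y/F.
_IDR_FREQS = {
    "S": 0.12, "P": 0.10, "G": 0.09, "E": 0.09, "K": 0.08, "Q": 0.07,
    "R": 0.06, "A": 0.08, "D": 0.06, "T": 0.06, "N": 0.05, "L": 0.04,
    "V": 0.03, "I": 0.02, "M": 0.01, "H": 0.02, "F": 0.005, "Y": 0.005,
    "C": 0.005, "W": 0.005,
}


def _draw_sequence(rng, length, freqs: dict) -> str:
    letters = list(freqs)
    p = np.array([freqs[a] for a in letters], dtype=float)
    p /= p.sum()
    return "".join(rng.choice(letters, size=length, p=p))


def gen_disorder(
    n_proteins: int = 60,
    class_proportions: dict | None = None,
    n_predictors: int = 8,
    agreement: float = 1.0,
    length_range: tuple = (200, 600),
    idr_fraction: dict | None = None,
    ryf_boost: float = 2.0,
    seed: int = 0,
) -> tuple[list, dict, pd.DataFrame]:
    """Simulate multi-predictor disorder tracks, sequences, and truth.

    Each protein carries one planted IDR whose fractional length depends on
    its class (stabilized proteins get longer IDRs, as thermally stabilized
    stress-granule proteins do); stabilized-class IDR sequences multiply
    their R/Y/F frequencies by ``ryf_boost``.  Each predictor reports the
    true per-residue state with probability ``agreement``.

    Returns (profiles, sequences by protein id, truth table with planted
    interval and class).
    """
    class_proportions = class_proportions or {
        "stabilized": 0.2, "destabilized": 0.2, "unaffected": 0.6,
    }
    idr_fraction = idr_fraction or {
        "stabilized": 0.45, "destabilized": 0.15, "unaffected": 0.25,
    }
    rng = derive_rng(seed, "disorder")
    classes = list(class_proportions)
    probs = np.array([class_proportions[c] for c in classes], dtype=float)
    probs /= probs.sum()

    profiles, sequences, records = [], {}, []
    for i in range(n_proteins):
        pid = f"SIM{i:04d}"
        cls = classes[rng.choice(len(classes), p=probs)]
        length = int(rng.integers(*length_range))
        idr_len = max(12, int(round(idr_fraction[cls] * length)))
        start = int(rng.integers(1, length - idr_len + 1))  # 1-based
        truth_state = np.zeros(length, dtype=bool)
        truth_state[start - 1 : start - 1 + idr_len] = True

        if agreement >= 1.0:
            calls = np.repeat(truth_state[:, None], n_predictors, axis=1)
        else:
            flips = rng.random((length, n_predictors)) > agreement
            calls = truth_state[:, None] ^ flips

        freqs = dict(_IDR_FREQS)
        if cls == "stabilized":
            for a in "RYF":
                freqs[a] *= ryf_boost
        idr_seq = _draw_sequence(rng, idr_len, freqs)
        flank = _draw_sequence(rng, length - idr_len, _AA_FREQS)
        seq = flank[: start - 1] + idr_seq + flank[start - 1 :]

        profiles.append(DisorderProfile(pid, calls, sequence=seq))
        sequences[pid] = seq
        records.append(
            {"protein_id": pid, "class": cls, "idr_start": start,
             "idr_end": start + idr_len - 1, "length": length}
        )
    truth = pd.DataFrame(records).set_index("protein_id")
    return profiles, sequences, truth


def _synthetic_protein(name: str, length: int, n_met: int) -> str:
    """Deterministic SYNTHETIC stand-in sequence: fixed length and Met count.

    Not a real protein sequence — a constructed surrogate with human-average
    amino-acid composition, the documented length, and exactly ``n_met``
    methionines at reproducible positions.
    """
    rng = derive_rng(12345, f"synthetic-protein-{name}")
    freqs = {a: f for a, f in _AA_FREQS.items() if a != "M"}
    seq = list(_draw_sequence(rng, length, freqs))
    for pos in rng.choice(length, size=n_met, replace=False):
        seq[pos] = "M"
    return "".join(seq)


def synthetic_sfpq() -> str:
    """SYNTHETIC stand-in for canonical human SFPQ: 707 aa, 28 methionines.

    The real protein is the splicing factor SFPQ (707 residues, 28 Met).
    This surrogate reproduces only those documented summary properties; it
    is not the canonical sequence and must not be used as one.
    """
    return _synthetic_protein("sfpq", 707, 28)


def synthetic_srsf1() -> str:
    """SYNTHETIC stand-in for canonical human SRSF1: 248 aa, 3 methionines.

    See :func:`synthetic_sfpq` for the construction and its limits.
    """
    return _synthetic_protein("srsf1", 248, 3)
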