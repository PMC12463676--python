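"""Consensus IDR calling and amino-acid composition enrichment.

A residue is consensus-disordered when strictly more than a configurable
fraction (default 75%) of the available per-residue disorder predictors
call it disordered; a maximal run of strictly more than ``min_run``
(default 10, i.e. >= 11 residues) consensus-disordered residues becomes an
intrinsically disordered region (IDR).  Per-protein IDR proportions are
compared between protein classes (e.g. thermally stabilized vs unaffected)
with two-sample rank tests under Holm correction, and the amino-acid
composition of class IDRs is scored against a background IDR set as the
relative frequency difference (f_group - f_bg)/f_bg with protein-level
bootstrap dispersion and per-residue-type t-tests under Bonferroni
correction.

Intervals are 1-based inclusive in all outputs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import derive_rng

__all__ = [
    "AMINO_ACIDS",
    "DisorderProfile",
    "IDRSet",
    "call_idrs",
    "idr_proportion_by_class",
    "composition_enrichment",
    "count_residue",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class DisorderProfile:
    """Per-residue boolean disorder calls of several predictors for one protein.

    calls : bool array, shape (length, n_predictors)
    sequence : optional amino-acid string of matching length
    """

    protein_id: str
    calls: np.ndarray
    sequence: str | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=bool)
        if self.calls.ndim != 2 or self.calls.shape[1] < 1:
            raise ValueError("calls must be (length, n_predictors) with >= 1 predictor")
        if self.sequence is not None and len(self.sequence) != self.calls.shape[0]:
            raise ValueError("sequence length does not match call track length")

    @property
    def length(self) -> int:
        return self.calls.shape[0]

    @property
    def n_predictors(self) -> int:
        return self.calls.shape[1]


@dataclass
class IDRSet:
    """IDR intervals (1-based inclusive, sorted, non-overlapping) of one protein."""

    protein_id: str
    length: int
    intervals: list = field(default_factory=list)

    @property
    def idr_proportion(self) -> float:
        total = sum(e - s + 1 for s, e in self.intervals)
        return total / self.length if self.length else 0.0

    def idr_sequences(self, sequence: str) -> list:
        return [sequence[s - 1 : e] for s, e in self.intervals]


def call_idrs(
    profile: DisorderProfile, consensus_frac: float = 0.75, min_run: int = 10
) -> IDRSet:
    """Call IDRs by strict consensus and strict run length.

    A residue is consensus-disordered iff its disordered-predictor fraction
    strictly exceeds ``consensus_frac`` (3 of 4 predictors is exactly 75%
    and does NOT pass the default); a maximal consensus run becomes an
    interval iff its length strictly exceeds ``min_run`` (a 10-residue run
    does not pass the default, an 11-residue run does).
    """
    frac = profile.calls.mean(axis=1)
    consensus = frac > consensus_frac
    intervals = []
    start = None
    for i, c in enumerate(consensus):
        if c and start is None:
            start = i
        elif not c and start is not None:
            if i - start > min_run:
                intervals.append((start + 1, i))
            start = None
    if start is not None and profile.length - start > min_run:
        intervals.append((start + 1, profile.length))
    return IDRSet(profile.protein_id, profile.length, intervals)


def idr_proportion_by_class(
    idrsets_by_class: dict,
    test: str = "ranksums",
    min_class_size: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class IDR-proportion distributions and pairwise Holm-adjusted p-values.

    ``idrsets_by_class`` maps a class label to a list of :class:`IDRSet`.
    ``test`` is ``"ranksums"`` (two-sample Mann-Whitney, default — the class
    groups are unpaired and of unequal size) or ``"wilcoxon"`` (paired
    signed-rank; only valid for equal-length paired groups).

    Returns (per-class summary table, pairwise comparison table).  Classes
    below ``min_class_size`` are summarised but excluded from comparisons.
    """
    props = {
        cls: np.array([s.idr_proportion for s in sets])
        for cls, sets in idrsets_by_class.items()
    }
    summary = pd.DataFrame(
        {
            "n": {c: len(v) for c, v in props.items()},
            "median_proportion": {c: float(np.median(v)) if len(v) else np.nan
                                  for c, v in props.items()},
            "mean_proportion": {c: float(np.mean(v)) if len(v) else np.nan
                                for c, v in props.items()},
        }
    )
    eligible = [c for c, v in props.items() if len(v) >= min_class_size]
    pairs, pvals = [], []
    for i, c1 in enumerate(eligible):
        for c2 in eligible[i + 1:]:
            if test == "ranksums":
                p = stats.mannwhitneyu(props[c1], props[c2], alternative="two-sided").pvalue
            elif test == "wilcoxon":
                p = stats.wilcoxon(props[c1], props[c2]).pvalue
            else:
                raise ValueError(f"unknown test {test!r}")
            pairs.append((c1, c2))
            pvals.append(float(p))
    if pairs:
        from statsmodels.stats.multitest import multipletests

        adj = multipletests(pvals, method="holm")[1]
    else:
        adj = []
    comparisons = pd.DataFrame(
        {
            "class_a": [a for a, _ in pairs],
            "class_b": [b for _, b in pairs],
            "p_value": pvals,
            "adjusted_p": adj,
        }
    )
    return summary, comparisons


def _aa_frequencies(sequences: list) -> tuple[pd.Series, int]:
    counts = Counter()
    for s in sequences:
        counts.update(s)
    total = sum(counts[a] for a in AMINO_ACIDS)
    freqs = pd.Series({a: counts[a] / total if total else np.nan for a in AMINO_ACIDS})
    return freqs, total


def composition_enrichment(
    group_sequences: list,
    background_sequences: list,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Amino-acid enrichment of group IDR sequences against a background.

    The score per residue type is (f_group - f_bg)/f_bg on pooled
    frequencies, so 0 means background-like, +1 a doubling and -1 complete
    depletion; ``(1 + score) * f_bg`` reconstructs the observed group
    frequency exactly.  Dispersion is the SD of the score under a
    protein-level bootstrap of the group; significance is an unpaired
    t-test of per-sequence frequencies (group vs background) with
    Bonferroni correction across the 20 residue types.  Residue types
    absent from the background get NaN scores.
    """
    if not group_sequences or not background_sequences:
        raise ValueError("both sequence sets must be non-empty")
    f_grp, _ = _aa_frequencies(group_sequences)
    f_bg, _ = _aa_frequencies(background_sequences)
    score = (f_grp - f_bg) / f_bg
    score[f_bg == 0] = np.nan

    rng = derive_rng(seed, "composition-bootstrap")
    n = len(group_sequences)
    boot = np.empty((n_boot, len(AMINO_ACIDS)))
    seqs = np.array(group_sequences, dtype=object)
    for b in range(n_boot):
        sample = seqs[rng.integers(0, n, size=n)]
        fb, _ = _aa_frequencies(list(sample))
        boot[b] = ((fb - f_bg) / f_bg).to_numpy()
    dispersion = pd.Series(np.nanstd(boot, axis=0, ddof=1), index=list(AMINO_ACIDS))

    def per_seq_freq(seqs_):
        rows = []
        for s in seqs_:
            f, tot = _aa_frequencies([s])
            if tot:
                rows.append(f)
        return pd.DataFrame(rows)

    g = per_seq_freq(group_sequences)
    bgd = per_seq_freq(background_sequences)
    pvals = {}
    for a in AMINO_ACIDS:
        if f_bg[a] == 0:
            pvals[a] = np.nan
            continue
        pvals[a] = float(stats.ttest_ind(g[a], bgd[a], equal_var=False).pvalue)
    p = pd.Series(pvals)
    adjusted = (p * len(AMINO_ACIDS)).clip(upper=1.0)  # Bonferroni
    return pd.DataFrame(
        {
            "score": score,
            "dispersion": dispersion,
            "p_value": p,
            "adjusted_p": adjusted,
        }
    ).rename_axis("amino_acid")


def count_residue(sequence: str, residue: str) -> dict:
    """Count one residue type in a protein sequence.

    Returns the count, the sequence length, and any non-standard letters
    encountered (counted separately, never silently dropped).
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    seq = sequence.upper()
    nonstandard = Counter(c for c in seq if c not in AMINO_ACIDS)
    return {
        "residue": residue.upper(),
        "count": seq.count(residue.upper()),
        "length": len(seq),
        "nonstandard": dict(nonstandard),
    }
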