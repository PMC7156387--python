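"""96-channel mutation catalogues and reference-signature exposures.

A catalogue is the count vector of a sample's SNVs over the 96
trinucleotide substitution channels. Exposures are obtained by
non-negative least squares against a reference signature matrix
(96 x K, columns summing to 1), with small weights pruned below
``min_weight`` and the fit repeated on the surviving signatures, mimicking
common sparse signature-refitting practice. Exposures are reported as
mutation fractions summing to one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .trinuc import CHANNELS, CHANNEL_INDEX

log = logging.getLogger(__name__)

MIN_STABLE_MUTATIONS = 20


@dataclass
class Catalogue96:
    sample_id: str
    counts: np.ndarray  # length 96, standard channel order

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("catalogue must have 96 channels")
        if (self.counts < 0).any():
            raise ValueError("negative channel counts")

    @property
    def n_mutations(self) -> int:
        return int(round(self.counts.sum()))


@dataclass
class SignatureExposure:
    sample_id: str
    weights: np.ndarray  # over reference signatures, >= 0, sums to 1
    signature_names: tuple[str, ...]
    reconstruction_cosine: float
    n_mutations: int
    stable: bool = True

    def as_percentages(self) -> dict[str, float]:
        return {n: 100.0 * w for n, w in zip(self.signature_names, self.weights)}


def synthetic_signature_matrix(n_signatures: int = 30, seed: int = 2020) -> pd.DataFrame:
    """Deterministic synthetic stand-in for a 30-signature 96-channel reference.

    This is NOT the published COSMIC matrix: it is a synthetic reference of
    the same shape whose first columns qualitatively mimic well-known
    processes (S1: C>T at NpCpG from 5-methylcytosine deamination; S3: a
    near-flat profile as in homologous-recombination deficiency; S4:
    C>A-dominated as in tobacco exposure), with the remaining columns drawn
    as sparse Dirichlet profiles. Use ``read_signature_matrix`` to supply
    the real published matrix for analyses of real data.
    """
    rng = np.random.default_rng(seed)
    cols = {}
    s1 = np.full(96, 1e-4)
    for i, name in enumerate(CHANNELS):
        if "[C>T]" in name and name.endswith("G"):
            s1[i] = 1.0
    cols["S1"] = s1 / s1.sum()
    s2 = np.full(96, 1e-4)
    for i, name in enumerate(CHANNELS):
        if name.startswith("T[C>") and ("C>T" in name or "C>G" in name):
            s2[i] = 1.0
    cols["S2"] = s2 / s2.sum()
    s3 = np.ones(96) + rng.uniform(0, 0.15, 96)  # near-flat
    cols["S3"] = s3 / s3.sum()
    s4 = np.full(96, 1e-4)
    for i, name in enumerate(CHANNELS):
        if "[C>A]" in name:
            s4[i] = 1.0 + 0.5 * (name[0] == "C")
    cols["S4"] = s4 / s4.sum()
    for k in range(5, n_signatures + 1):
        prof = rng.dirichlet(np.full(96, 0.08))
        cols[f"S{k}"] = prof
    mat = pd.DataFrame(cols, index=list(CHANNELS)).iloc[:, :n_signatures]
    return mat


def read_signature_matrix(path: str | Path) -> pd.DataFrame:
    """Read a reference matrix TSV: 96 rows labelled by channel, K columns."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(CHANNELS) - set(mat.index)
    if missing:
        raise ValueError(f"signature matrix missing channels: {sorted(missing)[:3]}...")
    mat = mat.loc[list(CHANNELS)]
    sums = mat.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("signature columns must each sum to 1")
    return mat


def write_signature_matrix(mat: pd.DataFrame, path: str | Path) -> None:
    mat.to_csv(path, sep="\t", index_label="channel")


def build_catalogue(variants, sample_id: str = "sample") -> Catalogue96:
    """Bin SNVs (``context96`` channel set) into a 96-channel catalogue.

    Indels and other context-free variants are excluded; the excluded count
    is logged.
    """
    counts = np.zeros(96)
    skipped = 0
    for v in variants:
        ctx = getattr(v, "context96", None) or (v if isinstance(v, str) else None)
        if not ctx:
            skipped += 1
            continue
        counts[CHANNEL_INDEX[ctx]] += 1
    if skipped:
        log.info("%s: excluded %d variants without trinucleotide context", sample_id, skipped)
    return Catalogue96(sample_id, counts)


def fit_exposures(
    catalogue: Catalogue96,
    reference: pd.DataFrame,
    min_weight: float = 0.06,
) -> SignatureExposure:
    """Sparse NNLS decomposition of a catalogue against reference signatures.

    The catalogue is normalised to channel frequencies and fitted by
    non-negative least squares; signatures whose normalised weight falls
    below ``min_weight`` are removed and the fit repeated on the survivors
    until all remaining weights clear the threshold. Final weights are
    normalised to sum to 1 and the cosine similarity between the catalogue
    and its reconstruction is reported.
    """
    S = reference.to_numpy(dtype=float)
    names = tuple(reference.columns)
    total = catalogue.counts.sum()
    if total == 0:
        raise ValueError("cannot fit an empty catalogue")
    stable = total >= MIN_STABLE_MUTATIONS
    if not stable:
        log.warning("%s: only %d mutations; exposure fit is unstable",
                    catalogue.sample_id, int(total))
    target = catalogue.counts / total

    active = np.arange(S.shape[1])
    while True:
        w_active, _ = optimize.nnls(S[:, active], target)
        norm = w_active.sum()
        w_norm = w_active / norm if norm > 0 else w_active
        if norm > 0 and (w_norm < min_weight).any() and len(active) > 1:
            active = active[w_norm >= min_weight]
            if len(active) == 0:  # keep the single best signature
                active = np.array([int(np.argmax(w_norm))])
            continue
        break
    weights = np.zeros(S.shape[1])
    weights[active] = w_norm
    recon = S @ weights
    denom = np.linalg.norm(recon) * np.linalg.norm(target)
    cosine = float(recon @ target / denom) if denom > 0 else 0.0
    return SignatureExposure(
        sample_id=catalogue.sample_id,
        weights=weights,
        signature_names=names,
        reconstruction_cosine=cosine,
        n_mutations=int(total),
        stable=stable,
    )


def dissect_temporally(
    snv_table: pd.DataFrame,
    reference: pd.DataFrame,
    min_weight: float = 0.06,
) -> dict[tuple[str, str], SignatureExposure]:
    """Exposures per (tumour class, clonality) stratum.

    ``snv_table`` needs columns context96, tumour_class ("primary" /
    "metastasis") and clonality ("clonal" / "subclonal"). Strata with
    fewer than 20 SNVs are fitted but flagged unstable; empty strata are
    omitted.
    """
    out = {}
    for (tclass, clon), sub in snv_table.groupby(["tumour_class", "clonality"]):
        contexts = [c for c in sub["context96"] if c]
        if not contexts:
            continue
        cat = build_catalogue(contexts, sample_id=f"{tclass}/{clon}")
        out[(tclass, clon)] = fit_exposures(cat, reference, min_weight)
    return out


def correlate_exposure_burden(exposure: "np.ndarray", burden: "np.ndarray") -> tuple[float, float]:
    """Spearman rank correlation between a signature's exposure and burden.

    Midranks for ties; the p-value is exact (full permutation enumeration)
    for n <= 9 and the usual t-approximation otherwise. Two-sided.
    """
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(burden, dtype=float)
    n = len(x)
    if n < 4 or len(y) != n:
        raise ValueError("need at least 4 paired observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)

    def _rho(a, b):
        a = a - a.mean()
        b = b - b.mean()
        denom = np.sqrt((a**2).sum() * (b**2).sum())
        return float(a @ b / denom) if denom > 0 else 0.0

    rho = _rho(rx, ry)
    if n <= 9:
        import itertools

        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_rho(rx, np.array(perm))) >= abs(rho) - 1e-12:
                count += 1
        p = count / total
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p
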