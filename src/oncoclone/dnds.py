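"""Trinucleotide-context-corrected dN/dS for somatic SNVs.

Every possible single-base substitution of a coding reference is
enumerated, classified by codon impact (synonymous / missense / nonsense)
and binned into the 96 pyrimidine-centred trinucleotide channels, giving a
site-opportunity matrix L (96 x 3). Per-channel mutation rates are
estimated from the observed synonymous counts with empirical-Bayes
shrinkage toward the global synonymous rate, and the dN/dS ratio for an
impact class c is

    (n_obs_c / n_exp_c) / (s_obs / s_exp)

with expected counts E_c = sum_j r_j * L[j, c]. Confidence intervals come
from the profile likelihood of the ratio under a two-Poisson model
(conditionally, a binomial in the observed nonsynonymous share).

Conventions: CDS input must be in-frame with unambiguous bases; the
trinucleotide context of the first and last base of each CDS is completed
with an 'A' placeholder (applied identically to site enumeration and to
simulated mutations, so neutral calibration is unaffected); a stop-to-stop
change counts synonymous and a stop-loss counts missense.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .trinuc import CHANNELS, channel_index

log = logging.getLogger(__name__)

IMPACTS = ("synonymous", "missense", "nonsense")
IMPACT_INDEX = {name: i for i, name in enumerate(IMPACTS)}

_CODON_TABLE = None


def _translate(codon: str) -> str:
    global _CODON_TABLE
    if _CODON_TABLE is None:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE = dict(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE[codon]


@dataclass
class SiteSpectrum:
    """Site-opportunity matrix: 96 channels x {synonymous, missense, nonsense}."""

    L: np.ndarray
    total_length: int  # summed CDS length in bases

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        if self.L.shape != (96, 3):
            raise ValueError("site spectrum must be 96 x 3")


@dataclass
class DndsEstimate:
    stratum: str
    impact: str
    n_obs: int
    s_obs: int
    n_exp: float
    s_exp: float
    ratio: float
    ci95: tuple[float, float]
    defined: bool = True


def classify_substitution(codon: str, pos_in_codon: int, alt: str) -> str:
    """Impact of substituting ``alt`` at ``pos_in_codon`` of ``codon``."""
    old_aa = _translate(codon)
    new = codon[:pos_in_codon] + alt + codon[pos_in_codon + 1:]
    new_aa = _translate(new)
    if new_aa == old_aa:
        return "synonymous"
    if new_aa == "*":
        return "nonsense"
    return "missense"  # includes stop-loss


def enumerate_cds_snvs(name: str, seq: str) -> Iterable[tuple[int, str, str]]:
    """All 3L possible SNVs of one CDS as (channel_index, impact, alt) triples."""
    seq = seq.upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"{name}: CDS length {len(seq)} not divisible by 3")
    if set(seq) - set("ACGT"):
        raise ValueError(f"{name}: ambiguous bases in CDS")
    padded = "A" + seq + "A"  # placeholder flanks for terminal contexts
    for i, ref in enumerate(seq):
        codon_start = (i // 3) * 3
        codon = seq[codon_start:codon_start + 3]
        context = padded[i:i + 3]
        for alt in "ACGT":
            if alt == ref:
                continue
            impact = classify_substitution(codon, i % 3, alt)
            yield channel_index(ref, alt, context), impact, alt


def build_site_spectrum(cds: Sequence[tuple[str, str]] | str | Path) -> SiteSpectrum:
    """Site-opportunity matrix from in-frame CDS sequences.

    ``cds`` is either a FASTA path or a sequence of (name, sequence) pairs.
    """
    records = read_cds_fasta(cds) if isinstance(cds, (str, Path)) else list(cds)
    L = np.zeros((96, 3))
    total = 0
    for name, seq in records:
        total += len(seq)
        for ch, impact, _ in enumerate_cds_snvs(name, seq):
            L[ch, IMPACT_INDEX[impact]] += 1
    return SiteSpectrum(L, total)


def read_cds_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def toy_cds(n_genes: int = 50, n_codons: int = 120, seed: int = 7) -> list[tuple[str, str]]:
    """Deterministic toy coding reference: stop-free in-frame sequences.

    Each gene starts with ATG followed by random sense codons (no internal
    or terminal stop codons, so nonsense changes are always sense-to-stop).
    """
    rng = np.random.default_rng(seed)
    stops = {"TAA", "TAG", "TGA"}
    sense = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
             if a + b + c not in stops]
    genes = []
    for g in range(n_genes):
        codons = ["ATG"] + [sense[i] for i in rng.integers(0, len(sense), n_codons - 1)]
        genes.append((f"toygene{g + 1:03d}", "".join(codons)))
    return genes


def simulate_neutral_mutations(
    spectrum: SiteSpectrum, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Observed-count matrix (96 x 3) under neutral, uniform-site mutation."""
    probs = (spectrum.L / spectrum.L.sum()).ravel()
    draws = rng.multinomial(n, probs)
    return draws.reshape(96, 3).astype(float)


def estimate_dnds(
    observed: np.ndarray,
    spectrum: SiteSpectrum,
    stratum: str = "all",
) -> list[DndsEstimate]:
    """dN/dS per impact class from observed counts and site opportunities.

    ``observed`` is a 96 x 3 matrix of mutation counts by channel and
    impact. Channel rates come from synonymous counts shrunk toward the
    global synonymous rate; each nonsynonymous class is compared with its
    expectation under those rates. A stratum with zero observed synonymous
    mutations is flagged undefined.
    """
    O = np.asarray(observed, dtype=float)
    if O.shape != (96, 3):
        raise ValueError("observed counts must be 96 x 3")
    L = spectrum.L
    syn = IMPACT_INDEX["synonymous"]
    s_obs = float(O[:, syn].sum())
    # per-channel rates shrunk toward the global synonymous rate; plain
    # additive smoothing toward rate 1 explodes channels with few or no
    # synonymous sites and badly biases the expectations
    l_syn_total = float(L[:, syn].sum())
    if s_obs > 0 and l_syn_total > 0:
        global_rate = s_obs / l_syn_total
        prior = 0.5
        rates = (O[:, syn] + prior) / (L[:, syn] + prior / global_rate)
    else:
        rates = np.zeros(96)
    s_exp = float(rates @ L[:, syn])
    out = []
    for impact in ("missense", "nonsense"):
        ci = IMPACT_INDEX[impact]
        n_obs = float(O[:, ci].sum())
        n_exp = float(rates @ L[:, ci])
        if s_obs == 0 or n_exp <= 0:
            out.append(DndsEstimate(stratum, impact, int(n_obs), int(s_obs),
                                    n_exp, s_exp, float("nan"), (float("nan"),) * 2,
                                    defined=False))
            continue
        ratio = (n_obs / n_exp) / (s_obs / s_exp)
        ci95 = _profile_ci(n_obs, s_obs, n_exp, s_exp)
        out.append(DndsEstimate(stratum, impact, int(n_obs), int(s_obs),
                                n_exp, s_exp, ratio, ci95))
    return out


def _profile_ci(n_obs, s_obs, n_exp, s_exp, level=0.95):
    """Profile-likelihood CI for the rate ratio of two Poisson counts.

    Conditional on the total, n_obs ~ Binomial(n_obs + s_obs, q) with
    q = w*n_exp / (w*n_exp + s_exp); the profile in w is the binomial
    likelihood in q, inverted at the chi-squared(1) cutoff.
    """
    total = n_obs + s_obs
    crit = stats.chi2.ppf(level, df=1)

    def dev(w):
        q = w * n_exp / (w * n_exp + s_exp)
        q = min(max(q, 1e-12), 1.0 - 1e-12)
        qhat = n_obs / total
        ll = lambda p: (n_obs * np.log(p) if n_obs else 0.0) + \
                       (s_obs * np.log1p(-p) if s_obs else 0.0)
        return 2.0 * (ll(qhat) - ll(q)) - crit

    what = (n_obs / n_exp) / (s_obs / s_exp)
    lo = 0.0
    if n_obs > 0:
        try:
            lo = float(optimize.brentq(dev, 1e-9, what))
        except ValueError:
            lo = 0.0
    hi = np.inf
    try:
        hi = float(optimize.brentq(dev, what, max(what * 100.0, 100.0)))
    except ValueError:
        hi = np.inf
    return (lo, hi)


def observed_matrix(impacts: Sequence[str], channels: Sequence[int]) -> np.ndarray:
    """Tally (channel, impact) pairs of observed SNVs into a 96 x 3 matrix."""
    O = np.zeros((96, 3))
    for impact, ch in zip(impacts, channels):
        if impact in IMPACT_INDEX:
            O[ch, IMPACT_INDEX[impact]] += 1
    return O


def stratify_dnds(
    mutations: "pd.DataFrame",
    spectrum: SiteSpectrum,
) -> list[DndsEstimate]:
    """dN/dS within clonality x tumour-class strata.

    ``mutations`` needs columns impact (synonymous/missense/nonsense),
    channel (0..95), clonality (clonal/subclonal) and tumour_class
    (primary/metastasis). Emits estimates for 'all' plus each stratum;
    strata without synonymous mutations come back flagged undefined.
    """
    import pandas as pd  # noqa: F401

    out = []
    subsets = {"all": mutations}
    for clon in ("clonal", "subclonal"):
        for tclass in ("primary", "metastasis"):
            mask = (mutations["clonality"] == clon) & (mutations["tumour_class"] == tclass)
            subsets[f"{clon}_{tclass}"] = mutations[mask]
    for name, sub in subsets.items():
        if len(sub) == 0:
            for impact in ("missense", "nonsense"):
                out.append(DndsEstimate(name, impact, 0, 0, 0.0, 0.0,
                                        float("nan"), (float("nan"),) * 2, defined=False))
            continue
        O = observed_matrix(sub["impact"].tolist(), sub["channel"].tolist())
        out.extend(estimate_dnds(O, spectrum, stratum=name))
    return out
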