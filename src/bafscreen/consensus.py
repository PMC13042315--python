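"""Genotype-likelihood consensus calling with phred-scaled Q40 masking.

A deliberately small caller: per site, binomial likelihoods for the
alternate-read count under hom-ref / het / hom-alt (allele fractions
``eps``, 0.5 and ``1 - eps``; haploid mode drops the het state), a flat
genotype prior, and a phred-scaled quality ``Q = -10*log10(1 - posterior)``
capped at 99. Calls with Q below the threshold (default 40, i.e. an
estimated error rate above 1 in 10,000) are masked to ``N`` and behave as
missing data downstream. Heterozygous calls are emitted as two-base IUPAC
ambiguity codes. No BAQ, strand or mapping-quality features: the downstream
questions this package asks depend only on the genotype category and the
Q40 mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .simulate import ReferenceGenome, SiteRecord

__all__ = [
    "ConsensusCall",
    "BaseComposition",
    "call_site",
    "call_records",
    "calls_to_frame",
    "consensus_fasta",
    "count_base_calls",
    "IUPAC_HET",
]

DEPTH_CAP = 100_000  # reads beyond this are ignored at a site
Q_THRESHOLD = 40
Q_MAX = 99
DEFAULT_ERROR_RATE = 0.002

IUPAC_HET = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}
HET_CODES = set(IUPAC_HET.values())


@dataclass
class ConsensusCall:
    chrom: str
    pos: int
    genotype: str  # hom-ref | het | hom-alt (diploid); ref | alt (haploid)
    base: str  # emitted IUPAC character ('N' when masked)
    quality: int
    masked: bool


@dataclass
class BaseComposition:
    """Counts of consensus base categories in a FASTA sequence."""

    hom_high_quality: int
    het_high_quality: int
    low_quality: int

    @property
    def total(self) -> int:
        return self.hom_high_quality + self.het_high_quality + self.low_quality


def _genotype_arrays(
    depth: np.ndarray, alt: np.ndarray, mode: str, error_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized genotype index (argmax posterior) and phred quality."""
    depth = np.minimum(depth, DEPTH_CAP)
    alt = np.minimum(alt, depth)
    if mode == "diploid":
        thetas = np.array([error_rate, 0.5, 1.0 - error_rate])
    elif mode == "haploid":
        thetas = np.array([error_rate, 1.0 - error_rate])
    else:
        raise ValueError(f"mode must be haploid or diploid, got {mode!r}")
    # binomial log-likelihoods up to the (shared) combinatorial factor
    ll = alt[:, None] * np.log(thetas)[None, :] + (depth - alt)[:, None] * np.log(
        1.0 - thetas
    )[None, :]
    g = ll.argmax(axis=1)
    tot = logsumexp(ll, axis=1)
    # log(1 - posterior of best) = log(sum of the others) - log(sum of all)
    best = ll[np.arange(ll.shape[0]), g]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.exp(best - tot)  # posterior of the best genotype
        rest = tot + np.log1p(-np.minimum(ratio, 1.0))
        q = -10.0 * (rest - tot) / np.log(10.0)
    q = np.where(np.isfinite(q), q, Q_MAX)
    q = np.minimum(np.rint(q), Q_MAX).astype(int)
    q[depth == 0] = 0
    return g, q


def call_site(
    depth: int,
    alt_depth: int,
    mode: str = "diploid",
    error_rate: float = DEFAULT_ERROR_RATE,
    q_threshold: int = Q_THRESHOLD,
    ref: str = "A",
    alt: str = "G",
    chrom: str = "chr",
    pos: int = 1,
) -> ConsensusCall:
    """Call one site from its read counts.

    Depth 0 yields a masked call with Q=0. The genotype is the posterior
    argmax under a flat prior; the call is masked when Q falls below
    `q_threshold`.
    """
    if depth < 0 or not 0 <= alt_depth <= max(depth, 0):
        raise ValueError("need 0 <= alt_depth <= depth")
    if depth == 0:
        return ConsensusCall(chrom, pos, "masked", "N", 0, True)
    g, q = _genotype_arrays(
        np.array([depth]), np.array([alt_depth]), mode, error_rate
    )
    gi, qi = int(g[0]), int(q[0])
    if mode == "diploid":
        names = ["hom-ref", "het", "hom-alt"]
        bases = [ref, IUPAC_HET.get(frozenset({ref, alt}), "N"), alt]
    else:
        names = ["ref", "alt"]
        bases = [ref, alt]
    masked = qi < q_threshold
    return ConsensusCall(
        chrom, pos, names[gi], "N" if masked else bases[gi], qi, masked
    )


def call_records(
    records: list[SiteRecord],
    mode: str = "diploid",
    error_rate: float = DEFAULT_ERROR_RATE,
    q_threshold: int = Q_THRESHOLD,
) -> list[ConsensusCall]:
    """Vectorized consensus calling over a list of site records."""
    if not records:
        return []
    depth = np.array([r.depth for r in records])
    alt = np.array([r.alt_depth for r in records])
    g, q = _genotype_arrays(depth, alt, mode, error_rate)
    out = []
    if mode == "diploid":
        names = ("hom-ref", "het", "hom-alt")
    else:
        names = ("ref", "alt")
    for r, gi, qi in zip(records, g, q):
        masked = qi < q_threshold
        if mode == "diploid":
            bases = (r.ref, IUPAC_HET.get(frozenset({r.ref, r.alt}), "N"), r.alt)
        else:
            bases = (r.ref, r.alt)
        out.append(
            ConsensusCall(
                r.chrom, r.pos, names[gi], "N" if masked else bases[gi], int(qi), masked
            )
        )
    return out


def calls_to_frame(calls: list[ConsensusCall]):
    """Per-site calls as a VCF-like table with genotype and quality columns."""
    import pandas as pd

    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in calls],
            "pos": [c.pos for c in calls],
            "genotype": [c.genotype for c in calls],
            "base": [c.base for c in calls],
            "quality": [c.quality for c in calls],
            "masked": [c.masked for c in calls],
        }
    )


def consensus_fasta(
    calls: list[ConsensusCall], reference: ReferenceGenome
) -> dict[str, str]:
    """Per-chromosome consensus sequences: reference bases at uncalled sites,
    IUPAC codes at heterozygous calls, 'N' at masked calls. Indels are never
    introduced, so lengths always equal the reference."""
    seqs = {name: list(reference.chrom_str(name)) for name in reference.names}
    for call in calls:
        if call.chrom not in seqs:
            raise KeyError(f"call on unknown chromosome {call.chrom!r}")
        if not 1 <= call.pos <= len(seqs[call.chrom]):
            raise IndexError(
                f"call position {call.chrom}:{call.pos} beyond reference length"
            )
        seqs[call.chrom][call.pos - 1] = call.base
    return {name: "".join(chars) for name, chars in seqs.items()}


def count_base_calls(sequence: str) -> BaseComposition:
    """Categorize consensus bases: ACGT = high-quality homozygous, two-base
    IUPAC codes = high-quality heterozygous, N/lowercase = low quality."""
    if not sequence:
        raise ValueError("empty sequence")
    hom = het = low = 0
    for i, ch in enumerate(sequence):
        if ch in "ACGT":
            hom += 1
        elif ch in HET_CODES:
            het += 1
        elif ch == "N" or ch.islower():
            low += 1
        else:
            raise ValueError(f"unknown character {ch!r} at position {i + 1}")
    return BaseComposition(hom, het, low)
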