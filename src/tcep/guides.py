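"""Cas9 target-site scanning and qPCR amplicon validation.

SpCas9 cleaves double-stranded DNA wherever a ~20-nt protospacer is followed
by an NGG protospacer-adjacent motif (PAM), producing a blunt double-strand
break exactly 3 bp 5' of the PAM on the protospacer strand. The broken-DNA
qPCR assay needs two amplicons per site: one whose amplification region spans
the cut (and contains the whole spacer, so the assay also sees repaired but
mutated molecules) and a reference amplicon that avoids the cut entirely.

Coordinates are 0-based throughout; intervals are half-open; ``cut_pos`` is
an inter-base index on the forward strand (a cut between bases ``i-1`` and
``i`` has ``cut_pos == i``), which makes "does this amplicon span the cut"
an unambiguous strict-interior test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Literal

import numpy as np
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}

CUT_OFFSET = 3  # blunt cut this many bp 5' of the PAM, on the PAM's strand


@dataclass(frozen=True)
class TargetSite:
    """A PAM-anchored candidate Cas9 site.

    ``spacer`` and ``pam`` are given on the site's own strand; ``pam_start``
    and ``cut_pos`` are forward-strand coordinates (``cut_pos`` inter-base).
    """

    seq_id: str
    strand: str  # "+" or "-"
    spacer: str
    pam: str
    pam_start: int
    cut_pos: int

    @property
    def spacer_len(self) -> int:
        return len(self.spacer)

    @property
    def spacer_interval(self) -> tuple[int, int]:
        """Forward-strand half-open interval covered by the spacer."""
        if self.strand == "+":
            return self.pam_start - self.spacer_len, self.pam_start
        return self.pam_start + len(self.pam), self.pam_start + len(self.pam) + self.spacer_len

    @property
    def footprint(self) -> tuple[int, int]:
        """Forward-strand half-open interval covering spacer plus PAM."""
        s0, s1 = self.spacer_interval
        if self.strand == "+":
            return s0, self.pam_start + len(self.pam)
        return self.pam_start, s1


@dataclass(frozen=True)
class AmpliconDesign:
    """A primer-pair amplification interval and its validity flags.

    A ``target_spanning`` amplicon must straddle the predicted cut and
    contain the full spacer; a ``reference`` amplicon must avoid the cut.
    Flags are ``None`` until :func:`validate_amplicon` fills them.
    """

    seq_id: str
    start: int
    end: int
    purpose: Literal["target_spanning", "reference"]
    spans_cut: bool | None = None
    contains_spacer: bool | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty amplicon interval [{self.start}, {self.end})")
        if self.purpose not in ("target_spanning", "reference"):
            raise ValueError(f"unknown amplicon purpose {self.purpose!r}")

    @property
    def is_valid(self) -> bool | None:
        if self.spans_cut is None or self.contains_spacer is None:
            return None
        if self.purpose == "target_spanning":
            return self.spans_cut and self.contains_spacer
        return not self.spans_cut


def _matches(window: str, pattern: str) -> bool:
    """IUPAC match, rejecting windows that contain literal ambiguity codes."""
    for base, pat in zip(window, pattern):
        if base not in "ACGT" or base not in _IUPAC[pat]:
            return False
    return True


def scan_pam_sites(
    sequence: str,
    spacer_len: int = 20,
    pam: str = "NGG",
    strands: Literal["forward", "reverse", "both"] = "both",
    seq_id: str = "",
) -> list[TargetSite]:
    """Find every spacer+PAM context on the requested strands.

    Returns one :class:`TargetSite` per position where the strand-local
    sequence reads ``[spacer_len bases][PAM]``; sites whose spacer would run
    off the sequence are skipped, as are spacers containing N (with a
    warning — ambiguous bases cannot be targeted by qPCR primers). Results
    are sorted by ``pam_start``, forward strand first on ties.
    """
    if spacer_len < 17:
        raise ValueError(f"spacer_len must be >= 17, got {spacer_len}")
    if strands not in ("forward", "reverse", "both"):
        raise ValueError(f"unknown strands selection {strands!r}")
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-nucleotide characters: {sorted(bad)}")
    pam = pam.upper()
    if any(p not in _IUPAC for p in pam):
        raise ValueError(f"invalid PAM pattern {pam!r}")

    sites: list[TargetSite] = []
    length = len(seq)

    def scan_one(strand_seq: str, strand: str) -> None:
        for p in range(spacer_len, len(strand_seq) - len(pam) + 1):
            if not _matches(strand_seq[p : p + len(pam)], pam):
                continue
            spacer = strand_seq[p - spacer_len : p]
            if "N" in spacer:
                logger.warning(
                    "%s: skipping %s-strand site at local PAM position %d "
                    "(spacer contains N)",
                    seq_id or "<sequence>",
                    strand,
                    p,
                )
                continue
            if strand == "+":
                pam_start, cut_pos = p, p - CUT_OFFSET
            else:
                pam_start = length - p - len(pam)
                cut_pos = length - (p - CUT_OFFSET)
            sites.append(
                TargetSite(
                    seq_id=seq_id,
                    strand=strand,
                    spacer=spacer,
                    pam=strand_seq[p : p + len(pam)],
                    pam_start=pam_start,
                    cut_pos=cut_pos,
                )
            )

    if strands in ("forward", "both"):
        scan_one(seq, "+")
    if strands in ("reverse", "both"):
        scan_one(str(Seq(seq).reverse_complement()), "-")
    sites.sort(key=lambda s: (s.pam_start, s.strand))
    return sites


def validate_amplicon(design: AmpliconDesign, site: TargetSite) -> AmpliconDesign:
    """Fill a design's cut/spacer flags against one target site.

    ``spans_cut`` requires the inter-base cut strictly inside ``(start, end)``
    — an amplicon ending exactly at the cut does not span it and remains a
    valid reference. ``contains_spacer`` requires the spacer's forward-strand
    interval to lie within ``[start, end)``.
    """
    if design.seq_id != site.seq_id:
        raise ValueError(
            f"amplicon is on {design.seq_id!r} but site is on {site.seq_id!r}"
        )
    s0, s1 = site.spacer_interval
    return replace(
        design,
        spans_cut=design.start < site.cut_pos < design.end,
        contains_spacer=design.start <= s0 and s1 <= design.end,
    )


def reverse_complement(sequence: str) -> str:
    """Strand complement, reversed (delegates to Biopython)."""
    return str(Seq(sequence).reverse_complement())


def synthetic_site_fixture(
    n_sites: int = 3,
    spacer_len: int = 20,
    gap: int = 12,
    seed: int = 0,
    seq_id: str = "synthetic",
) -> tuple[str, list[TargetSite]]:
    """Build a synthetic sequence carrying exactly ``n_sites`` planted sites.

    The background and the spacers are drawn from {A, T} only and every PAM
    is TGG, so GG occurs solely inside planted PAMs and CC never occurs:
    the sequence contains exactly the planted forward-strand sites and no
    reverse-strand site. Returns the sequence and the expected site list
    (coordinates computed arithmetically from the construction, not by
    scanning).
    """
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    rng = np.random.default_rng(seed)

    def background(n: int) -> str:
        return "".join(rng.choice(["A", "T"], size=n))

    parts: list[str] = []
    sites: list[TargetSite] = []
    pos = 0
    for _ in range(n_sites):
        spacer = background(spacer_len)
        parts += [background(gap), spacer, "TGG"]
        pam_start = pos + gap + spacer_len
        sites.append(
            TargetSite(
                seq_id=seq_id,
                strand="+",
                spacer=spacer,
                pam="TGG",
                pam_start=pam_start,
                cut_pos=pam_start - CUT_OFFSET,
            )
        )
        pos = pam_start + 3
    parts.append(background(gap))
    return "".join(parts), sites
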