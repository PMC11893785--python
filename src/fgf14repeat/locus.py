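"""Model of the FGF14 intron-1 GAA repeat locus.

The locus is described by a :class:`LocusTemplate`: the fixed flanking
sequences on either side of the repeat tract, the three alternative anchor
sequences per side used to recognise locus-spanning reads, the two junction
20-mers used to size the repeat, the position of the rs534066520-like T>A
SNP in the upstream flank, and the six repeat motifs that make up pure and
complex tract configurations.

The template is a faithful model of the *printed* anchor and junction
sequences, not of the GRCh38 genomic phase: the flanks are constructed so
that (i) each anchor occurs exactly once in its own flank and never in the
other, (ii) a tract beginning with at least one GAA unit creates the
upstream junction 20-mer verbatim, and (iii) a tract ending with at least
two GAA units creates the downstream junction 20-mer verbatim.  The unit
accounting downstream (one unit inside the upstream junction, two inside
the downstream one) is calibrated by round-trip tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class LocusError(Exception):
    """Base error for locus-template problems."""


class TemplateError(LocusError):
    """A constructed template violates a structural invariant."""


class UnknownMotifError(LocusError):
    """A repeat block names a motif outside the template lexicon."""


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


#: The three alternative anchor sequences upstream of the repeat tract.
UP_ANCHORS: tuple[str, str, str] = (
    "TGCAAATGAAGGAAAACTCTTA",
    "TCTTAGTTGTAAAATATCAATA",
    "TTCTCTATGCAACCAACTTT",
)

#: The three alternative anchor sequences downstream of the repeat tract.
DOWN_ANCHORS: tuple[str, str, str] = (
    "GAAATGTGTTTAAGAATTCCTCAA",
    "TAAGACTAAGCTCTATGTGGG",
    "CAGGAACTGCTTAATTCATCATTG",
)

#: Junction 20-mer spanning the upstream flank/tract boundary.
JUNCTION_UP = "AACCAACTTTCTGTGAAGAA"

#: Junction 20-mer spanning the tract/downstream flank boundary.
JUNCTION_DOWN = "GAAGAATAGAAATGTGTTTA"

#: Repeat motif lexicon, ordered longest-first (the greedy tokenizer relies
#: on this order; the two 9-mers keep (GCA)2GAA before GCA(GAA)2).
MOTIFS: tuple[str, ...] = (
    "GCAGAAGAAGAAGAA",  # GCA(GAA)4
    "GCAGAAGAAGAA",     # GCA(GAA)3
    "GCAGCAGAA",        # (GCA)2GAA
    "GCAGAAGAA",        # GCA(GAA)2
    "GCAGAA",
    "GAA",
)

# Upstream flank: anchors 1 and 2 overlap by their shared "TCTTA", then a
# fixed non-repetitive spacer carrying the SNP site, then anchor 3 extended
# so the flank ends "...AACCAACTTTCTGTGAA" (last 17 nt of the upstream
# junction 20-mer).
_UP_SPACER = "CCTCCATTCGCTC"
_UP_FLANK = (
    "TGCAAATGAAGGAAAACTCTTAGTTGTAAAATATCAATA"  # anchors 1+2 merged (39 nt)
    + _UP_SPACER                                # 13 nt, SNP at index 6
    + "TTCTCTATGCAACCAACTTTCTGTGAA"             # anchor 3 extended (27 nt)
)
_SNP_OFFSET = 39 + 6  # the "T" inside the spacer

# Downstream flank: the printed 26-nt head (which contains anchor 1 from
# position 2) followed directly by anchors 2 and 3; the three pieces abut.
_DOWN_FLANK = (
    "TAGAAATGTGTTTAAGAATTCCTCAA"
    + "TAAGACTAAGCTCTATGTGGG"
    + "CAGGAACTGCTTAATTCATCATTG"
)


@dataclass(frozen=True)
class LocusTemplate:
    """Shared description of the repeat locus used by every pipeline stage."""

    up_anchors: tuple[str, str, str] = UP_ANCHORS
    down_anchors: tuple[str, str, str] = DOWN_ANCHORS
    junction_up: str = JUNCTION_UP
    junction_down: str = JUNCTION_DOWN
    up_flank: str = _UP_FLANK
    down_flank: str = _DOWN_FLANK
    snp_offset: int = _SNP_OFFSET
    snp_wt: str = "T"
    snp_alt: str = "A"
    motif_lexicon: tuple[str, ...] = MOTIFS

    @property
    def up_anchor_offsets(self) -> tuple[int, ...]:
        """Start offset of each upstream anchor within ``up_flank``."""
        return tuple(self.up_flank.index(a) for a in self.up_anchors)

    def flank_length(self) -> int:
        return len(self.up_flank) + len(self.down_flank)


def validate_template(template: LocusTemplate) -> None:
    """Check every structural invariant of a template; raise on violation.

    Called by :func:`default_template`; also usable on custom templates.
    """
    t = template
    if t.junction_up != t.up_flank[-17:] + "GAA":
        raise TemplateError("upstream junction must be last 17 nt of up_flank + GAA")
    if t.junction_down != "GAAGAA" + t.down_flank[:14]:
        raise TemplateError("downstream junction must be GAAGAA + first 14 nt of down_flank")
    if t.flank_length() != 150:
        raise TemplateError(f"flanks must total 150 nt, got {t.flank_length()}")
    for anchor in t.up_anchors:
        if t.up_flank.count(anchor) != 1:
            raise TemplateError(f"anchor {anchor} must occur exactly once in up_flank")
        if anchor in t.down_flank:
            raise TemplateError(f"upstream anchor {anchor} occurs in down_flank")
    for anchor in t.down_anchors:
        if t.down_flank.count(anchor) != 1:
            raise TemplateError(f"anchor {anchor} must occur exactly once in down_flank")
        if anchor in t.up_flank:
            raise TemplateError(f"downstream anchor {anchor} occurs in up_flank")
    # anchors must appear in their listed order within the flank
    ups = [t.up_flank.index(a) for a in t.up_anchors]
    if ups != sorted(ups):
        raise TemplateError("upstream anchors out of order in up_flank")
    downs = [t.down_flank.index(a) for a in t.down_anchors]
    if downs != sorted(downs):
        raise TemplateError("downstream anchors out of order in down_flank")
    # motifs of length >= 6 must not occur in either flank (GAA itself
    # necessarily occurs in the printed anchors and is exempt; motifs are
    # T-free so no junction or anchor logic depends on this)
    for motif in t.motif_lexicon:
        if len(motif) < 6:
            continue
        if motif in t.up_flank or motif in t.down_flank:
            raise TemplateError(f"motif {motif} occurs in a flank")
    if t.up_flank[t.snp_offset] != t.snp_wt:
        raise TemplateError("template up_flank must carry the wild-type SNP base")
    # SNP site outside every anchor match and outside the junction match
    for anchor, start in zip(t.up_anchors, t.up_anchor_offsets):
        if start <= t.snp_offset < start + len(anchor):
            raise TemplateError("SNP site lies inside an anchor match")
    if len(t.up_flank) - 17 <= t.snp_offset:
        raise TemplateError("SNP site lies inside the junction match")
    # junction 20-mers must not pre-exist inside a flank
    for junc in (t.junction_up, t.junction_down):
        if junc in t.up_flank or junc in t.down_flank:
            raise TemplateError(f"junction {junc} occurs inside a flank")
    lengths = [len(m) for m in t.motif_lexicon]
    if lengths != sorted(lengths, reverse=True):
        raise TemplateError("motif lexicon must be ordered longest-first")


def default_template() -> LocusTemplate:
    """Return the validated default locus template."""
    template = LocusTemplate()
    validate_template(template)
    return template
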