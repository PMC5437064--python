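"""Linear lambda-phage substrate model: feature maps, cassette insertion,
nick-site scanning, and in-silico digests.

The 48,502-bp lambda genome is modeled as a linear coordinate system with
origin at the cosL end.  Coordinates are 0-based, half-open ``[start, end)``
base pairs; kilobase values in reports are ``bp / 1000`` rounded to 0.1 kb.
Engineered substrates place insertion cassettes at three sites (A, B, C)
inside dispensable segments of the genome, and a nicking cassette of three
closely spaced single-strand nick sites whose excised segment is replaced
by a synthetic oligonucleotide.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from Bio.Seq import Seq

__all__ = [
    "LAMBDA_LENGTH_BP",
    "SITE_CENTERS_BP",
    "PACKAGING_MIN_BP",
    "PACKAGING_MAX_BP",
    "BSPQI_MOTIF",
    "Feature",
    "GenomeMap",
    "Cassette",
    "NickingCassette",
    "DigestResult",
    "SubstrateError",
    "PackagingError",
    "build_lambda_map",
    "insert_cassette",
    "check_packaging",
    "scan_recognition_sites",
    "predict_strand_fragments",
    "digest_duplex",
    "site_a_ncoi_layout",
    "site_a_nicking_cassette",
]

LAMBDA_LENGTH_BP = 48502
#: Cassette insertion-site centers, bp from cosL (sites A, B, C).
SITE_CENTERS_BP = {"A": 21300, "B": 33500, "C": 45300}
#: Phage packaging tolerates 78-105% of the wild-type genome length.
PACKAGING_MIN_BP = 38000
PACKAGING_MAX_BP = 53000
#: Nt.BspQI recognition sequence (nicks the strand bearing the motif).
BSPQI_MOTIF = "GCTCTTC"

_FEATURE_KINDS = frozenset(
    {"insertion_site", "dispensable", "cassette", "recognition_site", "modification"}
)


class SubstrateError(ValueError):
    """Invalid substrate layout or digest input."""


class PackagingError(SubstrateError):
    """Substrate length outside the packagable 38-53 kb range."""


@dataclass(frozen=True)
class Feature:
    """A half-open interval ``[start_bp, end_bp)`` on the substrate.

    Point features (e.g. insertion-site centers) use ``start_bp == end_bp``.
    Strand is only meaningful for ``recognition_site`` features.
    """

    name: str
    start_bp: int
    end_bp: int
    kind: str
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in _FEATURE_KINDS:
            raise SubstrateError(
                f"feature {self.name!r}: unknown kind {self.kind!r}"
            )
        if not 0 <= self.start_bp <= self.end_bp:
            raise SubstrateError(
                f"feature {self.name!r}: invalid interval "
                f"[{self.start_bp}, {self.end_bp})"
            )
        if self.strand not in (None, "top", "bottom"):
            raise SubstrateError(
                f"feature {self.name!r}: strand must be 'top' or 'bottom'"
            )

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def center_bp(self) -> int:
        return (self.start_bp + self.end_bp) // 2


@dataclass(frozen=True)
class GenomeMap:
    """Linear substrate map: total length plus an ordered feature tuple."""

    length_bp: int = LAMBDA_LENGTH_BP
    features: tuple[Feature, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise SubstrateError("substrate length must be positive")
        for f in self.features:
            if f.end_bp > self.length_bp:
                raise SubstrateError(
                    f"feature {f.name!r} extends past substrate end "
                    f"({f.end_bp} > {self.length_bp})"
                )
        # Overlap is checked within a kind only: cassettes and sites
        # legitimately sit inside dispensable segments.
        by_kind: dict[str, list[Feature]] = {}
        for f in self.features:
            by_kind.setdefault(f.kind, []).append(f)
        for kind, feats in by_kind.items():
            feats = sorted(feats, key=lambda f: (f.start_bp, f.end_bp))
            for a, b in zip(feats, feats[1:]):
                if b.start_bp < a.end_bp:
                    raise SubstrateError(
                        f"overlapping {kind} features {a.name!r} and {b.name!r}"
                    )

    def feature(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise SubstrateError(f"no feature named {name!r}")

    def features_of_kind(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]

    @property
    def length_kb(self) -> float:
        return round(self.length_bp / 1000.0, 1)


@dataclass(frozen=True)
class Cassette:
    """A recombineering insert replacing native sequence at a target site.

    ``marker=None`` denotes restoration of native sequence (no cassette
    feature is recorded), which makes cassette insertion invertible.
    """

    insert_length_bp: int
    replaced_length_bp: int
    target_site: str
    marker: str | None = "kanR"
    homology_arm_bp: int = 200

    def __post_init__(self) -> None:
        if self.homology_arm_bp <= 0:
            raise SubstrateError("homology_arm_bp must be positive")
        if self.insert_length_bp < 0 or self.replaced_length_bp < 0:
            raise SubstrateError("cassette lengths must be non-negative")

    def inverse(self) -> "Cassette":
        """The replacement that undoes this insertion (restores native)."""
        return Cassette(
            insert_length_bp=self.replaced_length_bp,
            replaced_length_bp=self.insert_length_bp,
            target_site=self.target_site,
            marker=None,
            homology_arm_bp=self.homology_arm_bp,
        )


@dataclass(frozen=True)
class NickingCassette:
    """Three consecutive top-strand nick sites with 12-13 bp spacers.

    The three nicks liberate the native single-strand segment between the
    first and last nick (39 nt for the default spacing), which is replaced
    by a synthetic oligonucleotide carrying the desired structure.
    """

    nick_positions_bp: tuple[int, int, int]
    diagnostic_sites: tuple[tuple[str, int, bool], ...] = ()

    def __post_init__(self) -> None:
        p = self.nick_positions_bp
        if len(p) != 3 or not (p[0] < p[1] < p[2]):
            raise SubstrateError("nick positions must be three strictly increasing bp")

    @property
    def excised_nt(self) -> int:
        return self.nick_positions_bp[-1] - self.nick_positions_bp[0]


@dataclass(frozen=True)
class DigestResult:
    """Multiset of fragment lengths from a duplex or single-strand digest."""

    fragment_lengths_bp: tuple[int, ...]
    strand: str  # duplex | top | bottom

    def __post_init__(self) -> None:
        if self.strand not in ("duplex", "top", "bottom"):
            raise SubstrateError(f"invalid strand {self.strand!r}")
        if any(f <= 0 for f in self.fragment_lengths_bp):
            raise SubstrateError("fragment lengths must be positive")

    @property
    def total_bp(self) -> int:
        return sum(self.fragment_lengths_bp)

    @property
    def fragment_lengths_kb(self) -> tuple[float, ...]:
        return tuple(round(f / 1000.0, 1) for f in self.fragment_lengths_bp)


def build_lambda_map(overrides: list[Feature] | None = None) -> GenomeMap:
    """Default engineered-lambda map, or one built from an explicit layout.

    The default carries the three insertion-site centers (21.3, 33.5,
    45.3 kb from cosL), the 16-kb dispensable segment between gene
    products J and N, and the 1.6-kb dispensable segment between Rz and
    the cosR end.
    """
    if overrides is not None:
        return GenomeMap(LAMBDA_LENGTH_BP, tuple(overrides))
    feats = [
        Feature("site_A", 21300, 21300, "insertion_site"),
        Feature("site_B", 33500, 33500, "insertion_site"),
        Feature("site_C", 45300, 45300, "insertion_site"),
        Feature("dispensable_J_N", 18600, 34600, "dispensable"),
        Feature("dispensable_Rz_cosR", 46902, 48502, "dispensable"),
    ]
    return GenomeMap(LAMBDA_LENGTH_BP, tuple(feats))


def check_packaging(length_bp: int) -> None:
    """Raise :class:`PackagingError` unless the length fits a phage capsid."""
    if not PACKAGING_MIN_BP <= length_bp <= PACKAGING_MAX_BP:
        raise PackagingError(
            f"substrate of {length_bp} bp outside packagable range "
            f"[{PACKAGING_MIN_BP}, {PACKAGING_MAX_BP}] bp"
        )


def insert_cassette(genome: GenomeMap, cassette: Cassette) -> GenomeMap:
    """Replace native sequence centered on the target site with an insert.

    Downstream features shift by the net length change; the replaced
    interval is centered on the target-site coordinate.  The resulting
    length is validated against the packaging bound.
    """
    site = genome.feature(f"site_{cassette.target_site}") \
        if len(cassette.target_site) == 1 else genome.feature(cassette.target_site)
    center = site.center_bp
    repl = cassette.replaced_length_bp
    lo = center - repl // 2
    hi = lo + repl
    if lo < 0 or hi > genome.length_bp:
        raise SubstrateError("replaced interval outside substrate")
    delta = cassette.insert_length_bp - repl
    new_length = genome.length_bp + delta
    check_packaging(new_length)

    new_center = lo + cassette.insert_length_bp // 2
    feats: list[Feature] = []
    for f in genome.features:
        if f is site:
            feats.append(replace(f, start_bp=new_center, end_bp=new_center))
        elif f.kind == "cassette" and lo <= f.start_bp and f.end_bp <= hi:
            continue  # replaced by this insertion (or excised on restore)
        elif f.end_bp <= lo:
            feats.append(f)
        elif f.start_bp >= hi:
            feats.append(replace(f, start_bp=f.start_bp + delta, end_bp=f.end_bp + delta))
        else:  # straddles the replaced interval: interval stretches/shrinks
            feats.append(replace(f, end_bp=max(f.start_bp, f.end_bp + delta)))
    if cassette.marker is not None and cassette.insert_length_bp > 0:
        feats.append(
            Feature(
                f"cassette_{cassette.marker}_{cassette.target_site}",
                lo,
                lo + cassette.insert_length_bp,
                "cassette",
            )
        )
    return GenomeMap(new_length, tuple(feats))


_ACGT_RE = re.compile(r"^[ACGT]*$")


def scan_recognition_sites(sequence: str, motif: str) -> list[tuple[int, str]]:
    """All occurrences of a recognition motif on either strand.

    Bottom-strand sites are occurrences of the reverse complement of the
    motif in the given (top-strand) sequence; positions are 0-based starts
    on the top strand.  Overlapping occurrences are all reported.
    Ambiguity codes are rejected so that site counts are deterministic.
    """
    sequence = sequence.upper()
    motif = motif.upper()
    if not motif:
        raise SubstrateError("motif must be non-empty")
    for label, s in (("sequence", sequence), ("motif", motif)):
        if not _ACGT_RE.match(s):
            raise SubstrateError(f"{label} contains non-ACGT characters")
    rc = str(Seq(motif).reverse_complement())
    strands = [(motif, "top")]
    if rc != motif:  # palindromic motifs yield one site per position
        strands.append((rc, "bottom"))
    hits: list[tuple[int, str]] = []
    for m, strand in strands:
        start = sequence.find(m)
        while start != -1:
            hits.append((start, strand))
            start = sequence.find(m, start + 1)
    return sorted(hits)


def predict_strand_fragments(
    genome: GenomeMap,
    nicks: NickingCassette | None,
    insert_mode: str = "flap",
) -> dict[str, DigestResult]:
    """Strand-resolved fragment prediction for a denaturing (alkaline) gel.

    The bottom strand is never nicked and runs as one full-length band.
    ``mock`` mode (a complementary oligo perfectly replacing the excised
    segment, fully re-ligated) restores a single full-length top strand.
    ``flap`` and ``gap`` modes leave the top strand discontinuous at the
    cassette, producing the two fragments flanking the insert; the
    excised native nucleotides are absent from the top-strand total.
    """
    if insert_mode not in ("mock", "flap", "gap"):
        raise SubstrateError(f"unknown insert mode {insert_mode!r}")
    L = genome.length_bp
    bottom = DigestResult((L,), "bottom")
    if nicks is None:
        return {"top": DigestResult((L,), "top"), "bottom": bottom}
    first, _, last = nicks.nick_positions_bp
    if not (0 < first and last < L):
        raise SubstrateError("nick positions outside the substrate")
    if insert_mode == "mock":
        top = DigestResult((L,), "top")
    else:
        top = DigestResult((first, L - last), "top")
    return {"top": top, "bottom": bottom}


def digest_duplex(
    genome: GenomeMap,
    cut_positions: list[int],
    abolished: set[int] | frozenset[int] = frozenset(),
) -> DigestResult:
    """Duplex restriction digest with optionally abolished cut sites.

    Fragment lengths are successive differences over the sorted boundary
    set ``{0} | (cuts - abolished) | {length}``; they sum to the substrate
    length exactly.
    """
    cuts = list(cut_positions)
    if sorted(cuts) != cuts:
        raise SubstrateError("cut positions must be sorted")
    if len(set(cuts)) != len(cuts):
        raise SubstrateError("duplicate cut positions")
    if not set(abolished) <= set(cuts):
        raise SubstrateError("abolished sites must be a subset of cut positions")
    for c in cuts:
        if not 0 < c < genome.length_bp:
            raise SubstrateError(f"cut position {c} outside the substrate")
    boundaries = sorted({0, genome.length_bp, *(c for c in cuts if c not in abolished)})
    frags = tuple(b - a for a, b in zip(boundaries, boundaries[1:]))
    return DigestResult(frags, "duplex")


def site_a_nicking_cassette(first_nick_bp: int = 21300) -> NickingCassette:
    """Nicking cassette at site A: three nicks spaced one recognition
    sequence plus a 13/12-bp spacer apart (20 + 19 bp), excising 39 nt."""
    p = first_nick_bp
    return NickingCassette(
        nick_positions_bp=(p, p + 20, p + 39),
        diagnostic_sites=(("NcoI", p + 10, True), ("NotI", p + 25, True)),
    )


def site_a_ncoi_layout(first_nick_bp: int = 21300) -> tuple[list[int], set[int]]:
    """Diagnostic NcoI layout around the site-A nicking cassette.

    Three cuts delimit the informative gel bands: 2.0 kb and 0.8 kb
    fragments meet at the flap-proximal NcoI site inside the cassette.
    Oligo insertion converts that site to single-stranded DNA, abolishing
    it and merging the two fragments into a single 2.8-kb band.  Returns
    ``(cut_positions, abolished_by_insert)``.
    """
    proximal = first_nick_bp + 10  # inside the excised 39-nt window
    cuts = [proximal - 2000, proximal, proximal + 800]
    return cuts, {proximal}
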