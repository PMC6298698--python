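"""TEV-digestion band prediction for engineered β2 constructs.

The orthogonal validation of a disulfide topology: a TEV protease site
(ENLYFQG, cut between Q and G) inserted after loop residue 137 splits the
construct into an N-terminal and a C-terminal (HA-tagged) fragment.  Under
non-reducing conditions the two fragments stay covalently linked whenever
an intact disulfide spans the cut, so the ~13 kDa HA fragment appears on an
anti-HA blot only when every cut-spanning bond has been removed — by DTT,
or by mutating one of its half-cystines to serine.

Masses are SDS-PAGE-style apparent masses: average amino-acid masses plus
one water per chain, plus a calibrated per-site N-glycan mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd
from Bio.SeqUtils import molecular_weight

from .errors import FormatError

__all__ = [
    "TEV_SITE",
    "HA_TAG",
    "PAPER_TOPOLOGY_PAIRS",
    "ProteinConstruct",
    "PairingTopology",
    "BandPrediction",
    "build_construct",
    "resolve_cut_sites",
    "predict_bands",
    "ha_band_released",
    "spans_cut",
    "topology_band_truth_table",
    "release_signature",
    "all_perfect_matchings",
    "render_virtual_gel",
]

TEV_SITE = "ENLYFQG"      # cut between Q and G; G stays C-terminal
HA_TAG = "YPYDVPDYA"
WATER = 18.02             # Da per chain
GLYCAN_MASS_DEFAULT = 3000.0  # Da per occupied N-X-S/T site (calibration)

CYS_POSITIONS = (84, 97, 101, 105, 113, 142, 148, 174)
#: inferred topology: C1-C5, C3-C7, C6-C8 (base-sequence residue numbers)
PAPER_TOPOLOGY_PAIRS = frozenset({
    frozenset({84, 113}), frozenset({101, 148}), frozenset({142, 174}),
})


@dataclass(frozen=True)
class ProteinConstruct:
    """An engineered construct: base sequence + insertions + C-terminal tag.

    All cysteine and glycosylation bookkeeping uses 1-based base-sequence
    numbering (the C84..C174 labelling); ``base_to_construct`` maps it into
    construct coordinates past any insertions.
    """

    name: str
    base_sequence: str
    insertions: tuple[tuple[int, str], ...] = ()
    c_tag: str = HA_TAG
    glyco_sites: tuple[int, ...] = ()
    glycan_mass: float = GLYCAN_MASS_DEFAULT

    def __post_init__(self) -> None:
        for pos, _ in self.insertions:
            if not 0 <= pos <= len(self.base_sequence):
                raise ValueError(f"insertion position {pos} out of range")

    @property
    def sequence(self) -> str:
        seq = self.base_sequence
        for pos, ins in sorted(self.insertions, reverse=True):
            seq = seq[:pos] + ins + seq[pos:]
        return seq + self.c_tag

    def base_to_construct(self, pos: int) -> int:
        """Map a 1-based base-sequence residue to construct numbering."""
        if not 1 <= pos <= len(self.base_sequence):
            raise ValueError(f"base position {pos} out of range")
        offset = sum(len(ins) for at, ins in self.insertions if at < pos)
        return pos + offset


@dataclass(frozen=True)
class PairingTopology:
    """Disulfide pairs (base-numbering half-cystine positions) plus the set
    of cysteines mutated to serine.  A mutated position carries no edge."""

    pairs: frozenset[frozenset[int]]
    mutated_to_ser: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for pair in self.pairs:
            if len(pair) != 2:
                raise ValueError("each disulfide pair needs two positions")
            if pair & self.mutated_to_ser:
                raise ValueError("a mutated cysteine cannot carry a pair edge")
            if pair & seen:
                raise ValueError("a position may appear in at most one pair")
            seen |= pair

    def with_mutation(self, *positions: int) -> "PairingTopology":
        """Mutate cysteines to serine, dropping any edge they carried."""
        mut = self.mutated_to_ser | set(positions)
        kept = frozenset(p for p in self.pairs if not p & mut)
        return PairingTopology(kept, frozenset(mut))


@dataclass(frozen=True)
class BandPrediction:
    """Predicted blot bands for one (cleaved, reduced) condition."""

    fragments: tuple[tuple[int, int], ...]   # construct-coordinate intervals
    components: tuple[frozenset[int], ...]   # fragment indices per component
    masses: tuple[float, ...]                # Da per component
    ha_component: int | None                 # index of the HA-bearing component
    bands: tuple[tuple[float, bool], ...]    # (mass, contains_HA)
    cleaved: bool
    reduced: bool


def build_construct(
    base_seq: str,
    tev_after: int = 137,
    ha: bool = True,
    name: str = "pWT",
    glycan_mass: float = GLYCAN_MASS_DEFAULT,
    loop_region: tuple[int, int] = (46, 185),
) -> ProteinConstruct:
    """Insert the TEV site after ``tev_after`` and append the HA tag.

    N-glycosylation sequons (N-X-S/T, X ≠ P) are auto-detected within
    ``loop_region`` of the base sequence — only the extracellular loop is
    glycosylated in situ.
    """
    if len(base_seq) < tev_after:
        raise ValueError("base sequence shorter than the TEV insertion point")
    sites = tuple(
        i + 1 for i in range(len(base_seq) - 2)
        if base_seq[i] == "N" and base_seq[i + 1] != "P"
        and base_seq[i + 2] in "ST"
        and loop_region[0] <= i + 1 <= loop_region[1]
    )
    return ProteinConstruct(
        name=name, base_sequence=base_seq,
        insertions=((tev_after, TEV_SITE),),
        c_tag=HA_TAG if ha else "",
        glyco_sites=sites, glycan_mass=glycan_mass,
    )


def resolve_cut_sites(construct: ProteinConstruct,
                      protease: str = "TEV") -> tuple[int, ...]:
    """Construct positions of the residue N-terminal to each scissile bond
    (the Q of ENLYFQ/G; the G stays with the C-terminal fragment)."""
    if protease != "TEV":
        raise ValueError(f"unsupported protease {protease!r}")
    seq = construct.sequence
    cuts = []
    start = 0
    while (i := seq.find(TEV_SITE, start)) != -1:
        cuts.append(i + 6)  # 1-based position of Q
        start = i + 1
    return tuple(cuts)


def _chain_mass(seq: str) -> float:
    # average masses; biopython already adds one water per chain
    return float(molecular_weight(seq, "protein", monoisotopic=False))


def predict_bands(
    construct: ProteinConstruct,
    topology: PairingTopology,
    cleaved: bool = True,
    reduced: bool = False,
) -> BandPrediction:
    """Fragments, disulfide-linked components and their apparent masses.

    Fragments come from the cut sites (if cleaved); an intact disulfide
    (not reduced, neither half-cystine mutated) joins the fragments holding
    its two half-cystines; components are the connected components of that
    graph.  Component mass adds the glycan mass for every sequon it holds.
    """
    base = construct.base_sequence
    for pair in topology.pairs:
        for pos in pair:
            if pos in topology.mutated_to_ser:
                raise FormatError(
                    f"inconsistent topology: mutated Cys {pos} carries a pair")
            if base[pos - 1] != "C":
                raise FormatError(
                    f"topology position {pos} is {base[pos - 1]!r}, not Cys")
    seq = construct.sequence
    cuts = resolve_cut_sites(construct) if cleaved else ()
    bounds = (0,) + cuts + (len(seq),)
    fragments = tuple((bounds[i] + 1, bounds[i + 1])
                      for i in range(len(bounds) - 1))

    def frag_of(cpos: int) -> int:
        for i, (a, b) in enumerate(fragments):
            if a <= cpos <= b:
                return i
        raise AssertionError(cpos)

    g = nx.Graph()
    g.add_nodes_from(range(len(fragments)))
    if not reduced:
        for pair in topology.pairs:
            a, b = (construct.base_to_construct(p) for p in sorted(pair))
            g.add_edge(frag_of(a), frag_of(b))
    components = tuple(frozenset(c)
                       for c in sorted(nx.connected_components(g),
                                       key=min))
    glyco_cpos = [construct.base_to_construct(p) for p in construct.glyco_sites]
    masses = []
    ha_component: int | None = None
    for ci, comp in enumerate(components):
        m = sum(_chain_mass(seq[fragments[f][0] - 1: fragments[f][1]])
                for f in comp)
        m += construct.glycan_mass * sum(
            1 for gp in glyco_cpos if frag_of(gp) in comp)
        masses.append(m)
        if construct.c_tag and frag_of(len(seq)) in comp:
            ha_component = ci
    bands = tuple((m, ci == ha_component)
                  for ci, m in enumerate(masses))
    return BandPrediction(fragments, components, tuple(masses),
                          ha_component, bands, cleaved, reduced)


def ha_band_released(prediction: BandPrediction) -> bool:
    """True when the HA tag sits in a lone C-terminal fragment — the
    ~13 kDa band of an anti-HA blot."""
    if prediction.ha_component is None or not prediction.cleaved:
        return False
    if len(prediction.fragments) < 2:
        return False
    return len(prediction.components[prediction.ha_component]) == 1


def spans_cut(construct: ProteinConstruct, topology: PairingTopology,
              cut: int) -> bool:
    """Graph-cut criterion: does any intact disulfide straddle the cut?

    Release of the C-terminal fragment under non-reducing digestion is
    equivalent to *no* pair spanning the cut position (checked against the
    brute-force connected-components route in the test suite).
    """
    for pair in topology.pairs:
        a, b = sorted(construct.base_to_construct(p) for p in pair)
        if a <= cut < b:
            return True
    return False


def topology_band_truth_table(
    construct: ProteinConstruct,
    topology: PairingTopology,
    mutants: dict[str, tuple[int, ...]] | None = None,
) -> pd.DataFrame:
    """Predicted ±DTT release of the HA band for a panel of Cys→Ser mutants.

    ``mutants`` maps mutant name → mutated base positions; the default
    panel is the pseudo-wild-type plus every single Cys→Ser mutant.
    """
    if mutants is None:
        mutants = {"pWT": ()}
        mutants.update({f"C{i + 1}S": (pos,)
                        for i, pos in enumerate(CYS_POSITIONS)})
    rows = []
    for name, positions in mutants.items():
        topo = topology.with_mutation(*positions)
        minus = predict_bands(construct, topo, cleaved=True, reduced=False)
        plus = predict_bands(construct, topo, cleaved=True, reduced=True)
        ha_minus = minus.masses[minus.ha_component]
        ha_plus = plus.masses[plus.ha_component]
        rows.append({
            "mutant": name,
            "released_minus_dtt": ha_band_released(minus),
            "released_plus_dtt": ha_band_released(plus),
            "ha_mass_minus_dtt": round(ha_minus, 1),
            "ha_mass_plus_dtt": round(ha_plus, 1),
        })
    return pd.DataFrame(rows)


def release_signature(
    construct: ProteinConstruct,
    topology: PairingTopology,
    mutants: dict[str, tuple[int, ...]] | None = None,
) -> tuple[bool, ...]:
    """−DTT release pattern over a mutant panel; topologies sharing a
    signature are digestion-indistinguishable."""
    df = topology_band_truth_table(construct, topology, mutants)
    return tuple(bool(x) for x in df["released_minus_dtt"])


def all_perfect_matchings(
    positions: tuple[int, ...] = CYS_POSITIONS,
) -> list[frozenset[frozenset[int]]]:
    """All 105 perfect matchings of the eight loop cysteines."""
    def rec(rest: tuple[int, ...]):
        if not rest:
            yield frozenset()
            return
        first, tail = rest[0], rest[1:]
        for i, partner in enumerate(tail):
            for sub in rec(tail[:i] + tail[i + 1:]):
                yield sub | {frozenset({first, partner})}
    return list(rec(positions))


def render_virtual_gel(construct: ProteinConstruct,
                       topology: PairingTopology) -> str:
    """Plain-text anti-HA blot of the digestion experiment: undigested and
    digested lanes, each ±DTT, for the given construct/topology."""
    lanes = [
        ("uncut -DTT", False, False), ("uncut +DTT", False, True),
        ("TEV -DTT", True, False), ("TEV +DTT", True, True),
    ]
    lines = [f"virtual anti-HA blot — {construct.name}"]
    for label, cleaved, reduced in lanes:
        pred = predict_bands(construct, topology, cleaved, reduced)
        ha_bands = sorted((m for m, is_ha in pred.bands if is_ha),
                          reverse=True)
        marks = "  ".join(f"{m / 1000:5.1f} kDa" for m in ha_bands)
        lines.append(f"  {label:<11} | {marks}")
    return "\n".join(lines)
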