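"""Disulfide-pairing decision engine.

The β2 extracellular loop carries eight cysteines, labelled C1..C8
(residues 84, 97, 101, 105, 113, 142, 148 and 174).  The evidence per
mutant is a cohort summary — R_eq mean ± sd (n), q mean ± sd (n) and, for
charge probes, the per-subunit charge change Δq_e.  The procedure is:

1. split the eight single Cys→Ser mutants into a conserved (high-q) and a
   non-conserved (low-q) subgroup at the largest gap in q;
2. for a candidate pair (A, B), the three mutants C_AS, C_BS and C_AS/C_BS
   disrupt the same bond, so their R_eq cohorts should be statistically
   indistinguishable — tested by one-way ANOVA from the summary statistics;
3. enumerate perfect matchings within each subgroup, score each by its
   count of similar triplets, break ties by charge-probe support, and keep
   the pairs of the best matching whose triplets pass.

Charge probes (e.g. S173K with Δq_e = +1 next to C8) must shift R_eq in the
direction of Δq_e to count as consistent; they are used only as tie-break
support, mirroring their confirmatory role.
"""

from __future__ import annotations

import itertools
import json
import math
import re
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InferenceError
from .occupancy import MutantSummary

__all__ = [
    "CYSTEINE_MAP",
    "EvidenceTable",
    "TripletVerdict",
    "ChargeVerdict",
    "PairingResult",
    "anova_from_summary",
    "partition_by_q",
    "triplet_similarity",
    "charge_consistency",
    "infer_pairs",
    "simulate_evidence_panel",
]

#: label → residue number in the β2 sequence
CYSTEINE_MAP: dict[str, int] = {
    "C1": 84, "C2": 97, "C3": 101, "C4": 105,
    "C5": 113, "C6": 142, "C7": 148, "C8": 174,
}

_LABELS = tuple(CYSTEINE_MAP)

_CSV_COLUMNS = ["name", "req_mean", "req_sd", "req_n",
                "q_mean", "q_sd", "q_n", "dq_e", "cys_labels", "source"]


@dataclass(frozen=True)
class EvidenceTable:
    """The per-mutant evidence feeding the pairing rules."""

    rows: tuple[MutantSummary, ...]
    wt_name: str = "WT-beta2"

    def __post_init__(self) -> None:
        names = [r.name for r in self.rows]
        if len(set(names)) != len(names):
            raise ValueError("duplicate mutant names in evidence table")
        if self.wt_name not in names:
            raise ValueError(f"evidence table must contain a {self.wt_name} row")

    def __getitem__(self, name: str) -> MutantSummary:
        for r in self.rows:
            if r.name == name:
                return r
        raise KeyError(name)

    def get(self, name: str) -> MutantSummary | None:
        try:
            return self[name]
        except KeyError:
            return None

    @property
    def wt(self) -> MutantSummary:
        return self[self.wt_name]

    def by_labels(self, labels: frozenset[str]) -> MutantSummary | None:
        """The Cys→Ser mutant row whose mutated label set equals ``labels``
        (charge probes annotate nearby cysteines but are not Cys mutants)."""
        for r in self.rows:
            if _is_cys_mutant_name(r.name) and frozenset(r.cys_labels) == labels:
                return r
        return None

    def single_cys_rows(self) -> dict[str, MutantSummary]:
        return {r.cys_labels[0]: r for r in self.rows
                if len(r.cys_labels) == 1 and _is_cys_mutant_name(r.name)}

    # -- CSV round trip ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            d = asdict(r)
            d["cys_labels"] = ";".join(r.cys_labels)
            d["source"] = ""
            recs.append(d)
        return pd.DataFrame(recs)[_CSV_COLUMNS[:-1] + ["source"]]

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, wt_name: str = "WT-beta2") -> "EvidenceTable":
        df = pd.read_csv(path)
        missing = set(_CSV_COLUMNS[:-1]) - set(df.columns)
        if missing:
            raise ValueError(f"evidence table missing columns: {sorted(missing)}")
        rows = []
        for rec in df.to_dict("records"):
            labels = rec.get("cys_labels")
            labels = tuple(str(labels).split(";")) if isinstance(labels, str) \
                and labels else ()
            dq = rec.get("dq_e")
            dq = None if dq is None or (isinstance(dq, float)
                                        and math.isnan(dq)) else int(dq)
            rows.append(MutantSummary(
                name=str(rec["name"]),
                req_mean=float(rec["req_mean"]),
                req_sd=float(rec["req_sd"]), req_n=int(rec["req_n"]),
                q_mean=float(rec["q_mean"]) if not _isna(rec["q_mean"])
                else float("nan"),
                q_sd=float(rec["q_sd"]) if not _isna(rec["q_sd"])
                else float("nan"),
                q_n=int(rec["q_n"]) if not _isna(rec["q_n"]) else 0,
                dq_e=dq, cys_labels=labels,
            ))
        return cls(tuple(rows), wt_name=wt_name)


def _isna(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


_CYS_TOKEN = re.compile(r"C[1-8]S$")


def _is_cys_mutant_name(name: str) -> bool:
    parts = name.split("/")
    return bool(parts) and all(_CYS_TOKEN.match(p) for p in parts)


# ---------------------------------------------------------------------------
# summary-statistics inference
# ---------------------------------------------------------------------------

def anova_from_summary(
    groups: list[tuple[float, float, int]],
) -> tuple[float, float]:
    """One-way ANOVA (F, p) from per-group (mean, sd, n).

    F = [Σ nᵢ(x̄ᵢ − x̄)²/(k−1)] / [Σ (nᵢ−1)sᵢ²/(N−k)]; p is the upper tail
    of F(k−1, N−k).  Zero within-group variance with unequal means gives
    (inf, 0) exactly.  Equivalent to a raw-data ANOVA on any samples that
    realize the stated moments exactly.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(n < 2 for _, _, n in groups):
        raise ValueError("each group needs n >= 2")
    N = sum(n for _, _, n in groups)
    grand = sum(n * m for m, _, n in groups) / N
    ss_between = sum(n * (m - grand) ** 2 for m, _, n in groups)
    ss_within = sum((n - 1) * s**2 for _, s, n in groups)
    df1, df2 = k - 1, N - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    F = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(F, df1, df2))
    return float(F), p


def welch_from_summary(
    a: tuple[float, float, int], b: tuple[float, float, int],
) -> tuple[float, float]:
    """Welch two-sample t-test (t, two-sided p) from (mean, sd, n) pairs."""
    (m1, s1, n1), (m2, s2, n2) = a, b
    v1, v2 = s1**2 / n1, s2**2 / n2
    if v1 + v2 == 0.0:
        return (0.0, 1.0) if m1 == m2 else (float("inf"), 0.0)
    t = (m1 - m2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return t, p


# ---------------------------------------------------------------------------
# decision steps
# ---------------------------------------------------------------------------

def partition_by_q(table: EvidenceTable) -> dict[str, str]:
    """Two-cluster split of the eight single-mutant q means at the largest
    gap; the higher-q cluster is the conserved subgroup."""
    singles = table.single_cys_rows()
    missing = set(_LABELS) - set(singles)
    if missing:
        raise InferenceError(f"missing single-Cys rows: {sorted(missing)}")
    qs = sorted((singles[lbl].q_mean, lbl) for lbl in _LABELS)
    gaps = [qs[i + 1][0] - qs[i][0] for i in range(len(qs) - 1)]
    widest = int(np.argmax(gaps))
    if gaps[widest] <= 0.0:
        raise InferenceError("all q values equal: degenerate partition refused")
    low = {lbl for _, lbl in qs[: widest + 1]}
    return {lbl: ("non-conserved" if lbl in low else "conserved")
            for lbl in _LABELS}


@dataclass(frozen=True)
class TripletVerdict:
    a: str
    b: str
    F: float
    p: float
    verdict: str  # similar | dissimilar | untestable


@dataclass(frozen=True)
class ChargeVerdict:
    probe: str
    dq_e: int
    direction: str  # up | down | none
    p: float
    consistent: bool
    labels: tuple[str, ...]


def triplet_similarity(
    table: EvidenceTable, A: str, B: str, alpha: float = 0.05,
) -> TripletVerdict:
    """ANOVA across the R_eq cohorts of C_AS, C_BS and the double mutant.

    ``untestable`` (a missing row) is distinct from ``dissimilar`` and
    never counts for or against a candidate pair.
    """
    A, B = sorted((A, B), key=_LABELS.index)
    rows = [table.by_labels(frozenset({A})), table.by_labels(frozenset({B})),
            table.by_labels(frozenset({A, B}))]
    if any(r is None for r in rows):
        return TripletVerdict(A, B, float("nan"), float("nan"), "untestable")
    F, p = anova_from_summary([(r.req_mean, r.req_sd, r.req_n) for r in rows])
    return TripletVerdict(A, B, F, p, "similar" if p > alpha else "dissimilar")


def charge_consistency(
    table: EvidenceTable,
    probe: str,
    wt: str | None = None,
    alpha: float = 0.05,
) -> ChargeVerdict:
    """Does a charge probe shift R_eq in the direction of its Δq_e?

    A Welch test against the wild type classifies the shift as up, down or
    none; consistency requires the shift sign to match sign(Δq_e) (a null
    shift for Δq_e = 0).
    """
    row = table[probe]
    if row.dq_e is None:
        raise ValueError(f"probe {probe} has no dq_e annotation")
    wt_row = table[wt] if wt is not None else table.wt
    t, p = welch_from_summary((row.req_mean, row.req_sd, row.req_n),
                              (wt_row.req_mean, wt_row.req_sd, wt_row.req_n))
    direction = "none" if p > alpha else ("up" if t > 0 else "down")
    expected = {1: "up", -1: "down", 0: "none"}[int(np.sign(row.dq_e))]
    return ChargeVerdict(probe, row.dq_e, direction, p,
                         direction == expected, row.cys_labels)


def _perfect_matchings(labels: tuple[str, ...]):
    """All perfect matchings of an even label set (3 for four labels)."""
    if not labels:
        yield frozenset()
        return
    first, rest = labels[0], labels[1:]
    for i, partner in enumerate(rest):
        pair = frozenset({first, partner})
        remaining = rest[:i] + rest[i + 1:]
        for sub in _perfect_matchings(remaining):
            yield sub | {pair}


@dataclass(frozen=True)
class PairingResult:
    """Inferred disulfide topology plus the full decision log."""

    pairs: tuple[tuple[str, str], ...]
    unpaired: tuple[str, ...]
    subgroups: dict[str, str]
    triplet_log: tuple[TripletVerdict, ...]
    charge_log: tuple[ChargeVerdict, ...]
    best_matchings: dict[str, tuple[tuple[str, str], ...]]

    def residue_pairs(self) -> tuple[tuple[int, int], ...]:
        return tuple((CYSTEINE_MAP[a], CYSTEINE_MAP[b]) for a, b in self.pairs)

    def to_json(self, **kw) -> str:
        d = asdict(self)
        d["residue_pairs"] = [list(p) for p in self.residue_pairs()]
        return json.dumps(d, indent=2, default=_json_default, **kw)


def _json_default(o):
    if isinstance(o, float) and math.isnan(o):
        return None
    raise TypeError(type(o))


def infer_pairs(
    table: EvidenceTable,
    cys_map: dict[str, int] = CYSTEINE_MAP,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> PairingResult:
    """Deterministic pairing procedure over an evidence table.

    Within each q subgroup, every perfect matching is scored by its number
    of similar triplet verdicts; ties break on the number of consistent
    multi-site charge probes whose label pair appears in the matching, then
    lexicographically.  Pairs are the best matching's candidates whose
    triplets pass; every other label is reported unpaired.  All verdicts —
    including those for measured cross-subgroup doubles — are logged.
    """
    subgroups = partition_by_q(table)
    n_candidates = sum(
        math.comb(sum(1 for s in subgroups.values() if s == g), 2)
        for g in ("conserved", "non-conserved")
    )
    eff_alpha = alpha / n_candidates if bonferroni and n_candidates else alpha

    verdicts: dict[frozenset[str], TripletVerdict] = {}

    def verdict(a: str, b: str) -> TripletVerdict:
        key = frozenset({a, b})
        if key not in verdicts:
            verdicts[key] = triplet_similarity(table, a, b, alpha=eff_alpha)
        return verdicts[key]

    charge_log = tuple(
        charge_consistency(table, r.name, alpha=alpha)
        for r in table.rows if r.dq_e is not None
    )
    consistent_probe_pairs = [frozenset(v.labels) for v in charge_log
                              if v.consistent and len(v.labels) == 2]

    pairs: list[tuple[str, str]] = []
    best_matchings: dict[str, tuple[tuple[str, str], ...]] = {}
    for group in ("conserved", "non-conserved"):
        members = tuple(l for l in _LABELS if subgroups[l] == group)
        scored = []
        for matching in _perfect_matchings(members):
            score = sum(1 for pr in matching
                        if verdict(*sorted(pr, key=_LABELS.index)).verdict
                        == "similar")
            support = sum(1 for pp in consistent_probe_pairs if pp in matching)
            key = tuple(sorted(tuple(sorted(pr, key=_LABELS.index))
                               for pr in matching))
            scored.append((-score, -support, key, matching))
        if not scored:  # odd-sized subgroup: no perfect matching exists
            best_matchings[group] = ()
            continue
        scored.sort()
        _, _, key, best = scored[0]
        best_matchings[group] = key
        for pr in best:
            a, b = sorted(pr, key=_LABELS.index)
            if verdict(a, b).verdict == "similar":
                pairs.append((a, b))

    # log verdicts for every double-mutant row present, cross-subgroup ones
    # included (they can only ever count as diagnostics)
    for r in table.rows:
        if len(r.cys_labels) == 2 and _is_cys_mutant_name(r.name):
            verdict(*r.cys_labels)

    paired = {l for pr in pairs for l in pr}
    unpaired = tuple(l for l in _LABELS if l not in paired)
    return PairingResult(
        pairs=tuple(sorted(pairs)),
        unpaired=unpaired,
        subgroups=subgroups,
        triplet_log=tuple(verdicts[k] for k in sorted(
            verdicts, key=lambda k: tuple(sorted(k)))),
        charge_log=charge_log,
        best_matchings=best_matchings,
    )


# ---------------------------------------------------------------------------
# synthetic evidence panels (for validating the decision procedure)
# ---------------------------------------------------------------------------

def simulate_evidence_panel(
    true_pairs: tuple[tuple[str, str], ...],
    rng: np.random.Generator,
    wt_req: float = 1.85,
    effect_scale: tuple[float, float] = (0.20, 0.36),
    sd: float = 0.05,
    n_range: tuple[int, int] = (6, 8),
    sample_means: bool = False,
) -> tuple[EvidenceTable, tuple[tuple[str, str], ...]]:
    """Generate a full evidence panel from a known 4-bond topology.

    Each bond carries one R_eq perturbation δ ∈ −[0.20, 0.36] (breaking the
    bond shifts R_eq by δ, mutants disrupting the same bond shift alike);
    a double mutant across two bonds accumulates both δs.  The first two
    bonds are assigned conserved-subgroup q levels (≈0.42/0.58), the last
    two non-conserved levels (≈0.08/0.10).  Cohort sds ≈ ``sd`` and n in
    ``n_range`` mimic realistic panels; with ``sample_means`` the reported
    means additionally carry sd/√n sampling noise, as if each cohort were
    actually drawn.
    """
    if sorted(l for pr in true_pairs for l in pr) != sorted(_LABELS):
        raise ValueError("true_pairs must be a perfect matching of C1..C8")
    bond_of = {l: i for i, pr in enumerate(true_pairs) for l in pr}
    delta = {i: -rng.uniform(*effect_scale) for i in range(4)}
    q_level = {0: 0.42, 1: 0.58, 2: 0.08, 3: 0.10}

    def n_draw() -> int:
        return int(rng.integers(n_range[0], n_range[1] + 1))

    def summary(name, mean, qm, labels) -> MutantSummary:
        n, qn = n_draw(), n_draw()
        s = sd * rng.uniform(0.8, 1.2)
        qs = 0.05 * rng.uniform(0.8, 1.2)
        if sample_means:
            mean = mean + rng.normal(0.0, s / math.sqrt(n))
            qm = qm + rng.normal(0.0, qs / math.sqrt(qn))
        return MutantSummary(name, mean, s, n, qm, qs, qn,
                             cys_labels=labels)

    rows = [summary("WT-beta2", wt_req, 0.07, ())]
    for lbl in _LABELS:
        b = bond_of[lbl]
        rows.append(summary(f"{lbl}S", wt_req + delta[b],
                            q_level[b] + rng.uniform(-0.02, 0.02), (lbl,)))
    # doubles for every within-subgroup candidate pair
    subgroup = {l: ("conserved" if bond_of[l] < 2 else "non-conserved")
                for l in _LABELS}
    for a, b in itertools.combinations(_LABELS, 2):
        if subgroup[a] != subgroup[b]:
            continue
        ba, bb = bond_of[a], bond_of[b]
        mean = wt_req + (delta[ba] if ba == bb else delta[ba] + delta[bb])
        qm = max(q_level[ba], q_level[bb])
        rows.append(summary(f"{a}S/{b}S", mean, qm, (a, b)))
    truth = tuple(sorted(tuple(sorted(pr, key=_LABELS.index))
                         for pr in true_pairs))
    return EvidenceTable(tuple(rows)), truth
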