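"""Reciprocal-best-hit orthology with multi-criterion call assignment.

Candidates from each proteome are searched against the component reference
set (human and yeast exemplars) with exact Smith–Waterman local alignment;
raw scores become bit scores via the Karlin–Altschul transform and
e-values via E = m·n·2^(−bits). A candidate is called an orthologue of a
component when (1) its domain architecture matches the component template
with at least two domains in order, and (2) it and the component reference
are reciprocal best hits within the candidate's proteome. Clade placement
and length similarity are recorded as additional criteria — soft by
default, since genuinely divergent orthologues exist — and can be made
vetoing. Extra family members that fail only the reciprocal test are
called paralogues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from Bio import Align

from .domain_annotation import ARCHITECTURE_TEMPLATES, architecture_match
from .seqio_align import ProteinRecord, ScoringScheme

# Karlin-Altschul surrogate constants for gapped BLOSUM62 scoring
KA_LAMBDA = 0.267
KA_K = 0.041

EVALUE_PRESETS = {"default": 1e-5, "psiblast": 1e-15, "tblastn": 1e-30}


@dataclass(frozen=True)
class OrthologyCall:
    candidate_id: str
    species: str
    component: str | None
    architecture_ok: bool
    rbh_ok: bool
    clade_ok: bool | None
    length_ok: bool
    verdict: str  # orthologue | paralogue | rejected

    def as_row(self) -> tuple:
        return (self.candidate_id, self.species, self.component or "-",
                self.architecture_ok, self.rbh_ok,
                "-" if self.clade_ok is None else self.clade_ok,
                self.length_ok, self.verdict)


def bit_score(raw_score: float, lam: float = KA_LAMBDA, k: float = KA_K) -> float:
    return (lam * raw_score - math.log(k)) / math.log(2.0)


def e_value(bits: float, m: int, n: int) -> float:
    return m * n * (2.0 ** -bits)


def _score_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = scheme.matrix
    aligner.mode = "local"
    aligner.open_gap_score = -scheme.gap_open
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


def all_vs_all_search(
    queries: list[ProteinRecord],
    database: list[ProteinRecord],
    scheme: ScoringScheme | None = None,
    evalue_cutoff: float = 1e-5,
) -> pd.DataFrame:
    """Exact local-alignment search of every query against the database.

    Returns a hit table (query, subject, bitscore, evalue) with hits at or
    below the e-value cutoff, sorted by query then ascending e-value with
    lexicographic subject tie-break. Self-hits are reported like any other.
    """
    if not queries:
        raise ValueError("empty query set")
    if not database:
        raise ValueError("empty database")
    scheme = scheme or ScoringScheme()
    aligner = _score_aligner(scheme)
    total_residues = sum(len(r) for r in database)
    rows = []
    for query in sorted(queries, key=lambda r: r.id):
        for subject in sorted(database, key=lambda r: r.id):
            raw = aligner.score(query.sequence, subject.sequence)
            if raw <= 0:
                continue
            bits = bit_score(raw)
            ev = e_value(bits, len(query), total_residues)
            if ev <= evalue_cutoff:
                rows.append((query.id, subject.id, bits, ev))
    table = pd.DataFrame(rows, columns=["query", "subject", "bitscore", "evalue"])
    return table.sort_values(["query", "evalue", "subject"]).reset_index(drop=True)


def best_hits(hits: pd.DataFrame) -> dict[str, str]:
    """Best subject per query (lowest e-value; ties break to the
    lexicographically smallest subject id)."""
    best: dict[str, str] = {}
    for query, group in hits.groupby("query"):
        ordered = group.sort_values(["evalue", "subject"])
        best[query] = ordered.iloc[0]["subject"]
    return best


def reciprocal_best_hits(
    hits_ab: pd.DataFrame, hits_ba: pd.DataFrame
) -> list[tuple[str, str]]:
    """Pairs (a, b) where b is a's best hit and a is b's best hit."""
    if hits_ab.empty or hits_ba.empty:
        return []
    forward = best_hits(hits_ab)
    reverse = best_hits(hits_ba)
    pairs = [
        (a, b) for a, b in forward.items() if reverse.get(b) == a
    ]
    return sorted(pairs)


def assign_orthologue(
    candidate: ProteinRecord,
    component: str | None,
    rbh_ok: bool,
    annotations,
    references: dict[str, list[ProteinRecord]],
    clade_ok: bool | None = None,
    length_tolerance: float = 0.4,
    clade_hard: bool = False,
    length_hard: bool = False,
    has_significant_hit: bool = True,
) -> OrthologyCall:
    """Evaluate the four orthology criteria for one candidate.

    ``component`` is the complex component the candidate's best reference
    hit belongs to (None when no hit survived the cutoff). ``length_ok``
    holds when the candidate length is within ``length_tolerance`` of any
    exemplar of the component.
    """
    if component is not None and component not in references:
        raise KeyError(f"no reference exemplars for component {component!r}")
    if component is None:
        return OrthologyCall(candidate.id, candidate.species, None,
                             False, False, clade_ok, False, "rejected")
    arch = architecture_match(annotations, component, min_domains=2)
    length_ok = any(
        abs(len(candidate) - len(ref)) <= length_tolerance * len(ref)
        for ref in references[component]
    )
    ok = arch.matched and rbh_ok and has_significant_hit
    if clade_hard and clade_ok is False:
        ok = False
    if length_hard and not length_ok:
        ok = False
    if ok:
        verdict = "orthologue"
    elif arch.matched and has_significant_hit:
        verdict = "paralogue"
    else:
        verdict = "rejected"
    return OrthologyCall(candidate.id, candidate.species, component,
                         arch.matched, rbh_ok, clade_ok, length_ok, verdict)


def classify_proteomes(
    proteomes: dict[str, list[ProteinRecord]],
    references: dict[str, list[ProteinRecord]],
    annotations_by_protein: dict[str, list],
    scheme: ScoringScheme | None = None,
    evalue_cutoff: float = 1e-5,
    length_tolerance: float = 0.4,
    clade_results: dict[str, bool] | None = None,
    clade_hard: bool = False,
) -> list[OrthologyCall]:
    """Run search + RBH + criteria over whole proteomes.

    ``proteomes`` maps species to records; ``references`` maps component
    names to exemplar records. Reciprocity is evaluated within each
    species' proteome (each reference's best hit among that species'
    proteins must be the candidate).
    """
    scheme = scheme or ScoringScheme()
    ref_records = [r for recs in references.values() for r in recs]
    component_of_ref = {
        r.id: comp for comp, recs in references.items() for r in recs
    }
    calls: list[OrthologyCall] = []
    for species in sorted(proteomes):
        proteome = proteomes[species]
        if not proteome:
            continue
        forward = all_vs_all_search(proteome, ref_records, scheme, evalue_cutoff)
        reverse = all_vs_all_search(ref_records, proteome, scheme, evalue_cutoff)
        rbh = set(reciprocal_best_hits(forward, reverse))
        fwd_best = best_hits(forward)
        for candidate in sorted(proteome, key=lambda r: r.id):
            best_ref = fwd_best.get(candidate.id)
            component = component_of_ref.get(best_ref) if best_ref else None
            rbh_ok = component is not None and any(
                (candidate.id, ref.id) in rbh for ref in references.get(component, [])
            )
            clade_ok = clade_results.get(candidate.id) if clade_results else None
            calls.append(assign_orthologue(
                candidate, component, rbh_ok,
                annotations_by_protein.get(candidate.id, []),
                references, clade_ok, length_tolerance, clade_hard,
                has_significant_hit=best_ref is not None,
            ))
    return calls


def count_paralogues(calls: list[OrthologyCall]) -> pd.DataFrame:
    """Species × component counts of accepted family members.

    Counts calls with verdict orthologue or paralogue; absences are zero.
    """
    species = sorted({c.species for c in calls})
    components = list(ARCHITECTURE_TEMPLATES)
    counts = pd.DataFrame(0, index=species, columns=components)
    for call in calls:
        if call.verdict in ("orthologue", "paralogue") and call.component:
            counts.loc[call.species, call.component] += 1
    return counts


def calls_table(calls: list[OrthologyCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [c.as_row() for c in calls],
        columns=["candidate", "species", "component", "architecture_ok",
                 "rbh_ok", "clade_ok", "length_ok", "verdict"],
    )
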