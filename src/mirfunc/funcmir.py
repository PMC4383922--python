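"""Functional-miRNA identification by composite evidence scores.

Many miRBase entries are unlikely to be functional miRNAs (or are outright
false discoveries from high-throughput studies).  This module classifies
precursor miRNAs as functional by combining four independent evidence
criteria into a composite score:

(i)   *PubMed score* — repeated description in independent literature,
      operationalized as the number of distinct PubMed records associated
      with the precursor: 1 point for two records, 2 for three, 3 for four
      or more.
(ii)  *Conservation score* — presence of orthologous mature miRNAs in other
      species.  Because the 3'-end of a mature miRNA is post-transcriptionally
      modified and variable, an ortholog is defined by a perfect match of the
      5'-end 19 nt only: 1 point for one other species, 2 for two or more.
(iii) *Expression score* — pooled abundance across RNA-seq experiments in
      reads per million (RPM): 1 point for 1-10 RPM, 2 for over 10 RPM.
(iv)  *miRBase score* — 1 point if the precursor carries miRBase's
      "High Confidence" flag.

The composite is the sum (0-8); a composite of 3 or higher defines a
functional miRNA.  For each functional precursor the dominantly expressed
mature arm is selected, plus a secondary arm when its expression is no less
than 10% of the dominant arm's and no less than 5 RPM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .errors import ValidationError
from .mirbase_io import (
    Arm,
    ExpressionTable,
    MatureRecord,
    PrecursorRecord,
    PubmedMap,
)

CRITERIA = ("pubmed", "conservation", "expression", "mirbase")


@dataclass(frozen=True)
class ScoringParams:
    """Thresholds of the four-criterion scoring scheme.

    Defaults are the published brackets; every field can be overridden for
    sensitivity analyses, but the defaults define the reference procedure.
    """

    #: PMID-count thresholds earning 1, 2 and 3 points.
    pubmed_brackets: tuple[int, ...] = (2, 3, 4)
    #: Ortholog-species-count thresholds earning 1 and 2 points.
    conservation_brackets: tuple[int, ...] = (1, 2)
    #: RPM thresholds earning 1 and 2 points; the upper bracket is strict (>).
    expression_brackets_rpm: tuple[float, ...] = (1.0, 10.0)
    #: Composite score at or above which a precursor is called functional.
    functional_threshold: int = 3
    #: 5'-prefix length whose perfect match defines orthologous matures.
    ortholog_prefix_len: int = 19
    #: Secondary arm must reach this fraction of the dominant arm's RPM.
    secondary_fraction: float = 0.10
    #: ... and at least this absolute RPM.
    secondary_min_rpm: float = 5.0
    #: "pooled": total counts / total library size; "mean": mean of per-experiment RPM.
    rpm_aggregation: str = "pooled"

    def __post_init__(self) -> None:
        for name in ("pubmed_brackets", "conservation_brackets", "expression_brackets_rpm"):
            brackets = getattr(self, name)
            if list(brackets) != sorted(brackets) or len(set(brackets)) != len(brackets):
                raise ValidationError(f"{name} must be strictly ascending: {brackets}")
            if any(b <= 0 for b in brackets):
                raise ValidationError(f"{name} must be positive: {brackets}")
        if self.rpm_aggregation not in ("pooled", "mean"):
            raise ValidationError(
                f"rpm_aggregation must be 'pooled' or 'mean', got {self.rpm_aggregation!r}"
            )


DEFAULT_PARAMS = ScoringParams()


@dataclass(frozen=True)
class CriterionScores:
    """The four integer criterion scores for one precursor."""

    pubmed: int
    conservation: int
    expression: int
    mirbase: int

    def __post_init__(self) -> None:
        ranges = {"pubmed": 3, "conservation": 2, "expression": 2, "mirbase": 1}
        for name, upper in ranges.items():
            value = getattr(self, name)
            if not 0 <= value <= upper:
                raise ValidationError(f"{name} score {value} outside 0-{upper}")

    @property
    def composite(self) -> int:
        """Sum of the four criterion scores, 0-8."""
        return self.pubmed + self.conservation + self.expression + self.mirbase

    def as_dict(self) -> dict[str, int]:
        return {c: getattr(self, c) for c in CRITERIA}


@dataclass(frozen=True)
class FunctionalCall:
    """Classification outcome for one precursor."""

    precursor_id: str
    scores: CriterionScores
    is_functional: bool
    dominant_mature_id: Optional[str]
    secondary_mature_id: Optional[str]
    n_supporting_criteria: int
    required_criteria: frozenset[str] = field(default_factory=frozenset)


# ---------------------------------------------------------------------------
# Criterion scores
# ---------------------------------------------------------------------------


def pubmed_score(n_records: int, params: ScoringParams = DEFAULT_PARAMS) -> int:
    """Literature score from the number of distinct associated PubMed records."""
    if n_records < 0:
        raise ValidationError(f"negative PubMed record count {n_records}")
    return sum(n_records >= b for b in params.pubmed_brackets)


def conservation_score(
    n_ortholog_species: int, params: ScoringParams = DEFAULT_PARAMS
) -> int:
    """Conservation score from the number of other species with an ortholog."""
    if n_ortholog_species < 0:
        raise ValidationError(f"negative ortholog-species count {n_ortholog_species}")
    return sum(n_ortholog_species >= b for b in params.conservation_brackets)


def expression_score(rpm: float, params: ScoringParams = DEFAULT_PARAMS) -> int:
    """Expression score from pooled reads-per-million.

    The lower bracket is inclusive on both ends (1-10 RPM scores 1); the
    upper is strict (over 10 RPM scores 2).
    """
    if rpm < 0:
        raise ValidationError(f"negative RPM {rpm}")
    low, high = params.expression_brackets_rpm
    return int(rpm >= low) + int(rpm > high)


def mirbase_score(high_confidence: bool) -> int:
    """1 if the precursor carries miRBase's High Confidence flag, else 0."""
    return int(bool(high_confidence))


# ---------------------------------------------------------------------------
# Orthology
# ---------------------------------------------------------------------------


def _prefixes_match(a: str, b: str, prefix_len: int) -> bool:
    k = min(prefix_len, len(a), len(b))
    return a[:k] == b[:k]


def find_orthologs(
    mature: MatureRecord,
    foreign_sets: Mapping[str, Sequence[MatureRecord]],
    params: ScoringParams = DEFAULT_PARAMS,
) -> set[str]:
    """Species (other than the query's own) holding a 5'-prefix ortholog.

    Two matures are orthologous when their 5' prefixes are identical over
    ``min(prefix_len, len(a), len(b))`` nt — the 3' ends are ignored because
    they are variable under post-transcriptional modification.
    """
    if not mature.sequence:
        raise ValidationError(f"mature {mature.name}: empty sequence")
    hits: set[str] = set()
    for sp, candidates in foreign_sets.items():
        if sp == mature.species:
            continue
        for cand in candidates:
            if _prefixes_match(mature.sequence, cand.sequence, params.ortholog_prefix_len):
                hits.add(sp)
                break
    return hits


def build_orthology_map(
    matures: Sequence[MatureRecord], params: ScoringParams = DEFAULT_PARAMS
) -> dict[str, set[str]]:
    """Ortholog species sets for every mature, keyed by mature ID."""
    by_species: dict[str, list[MatureRecord]] = {}
    for mat in matures:
        by_species.setdefault(mat.species, []).append(mat)
    return {mat.id: find_orthologs(mat, by_species, params) for mat in matures}


# ---------------------------------------------------------------------------
# Expression aggregation
# ---------------------------------------------------------------------------


def pooled_rpm(table: ExpressionTable, mature_id: str) -> float:
    """Reads per million with all experiments pooled.

    1e6 x (sum of the mature's counts across experiments) / (sum of all
    library sizes).  A mature absent from the table has 0 RPM.
    """
    total_library = int(table.library_sizes.sum())
    if total_library <= 0:
        raise ValidationError("total library size must be positive")
    total_counts = int(table.counts_for(mature_id).sum())
    return 1e6 * total_counts / total_library


def mean_rpm(table: ExpressionTable, mature_id: str) -> float:
    """Mean over experiments of per-experiment RPM (alternative aggregation)."""
    if len(table.library_sizes) == 0:
        raise ValidationError("expression table has no experiments")
    counts = table.counts_for(mature_id)
    per_exp = 1e6 * counts / table.library_sizes
    return float(per_exp.mean())


def aggregate_rpm(
    table: ExpressionTable, mature_id: str, params: ScoringParams = DEFAULT_PARAMS
) -> float:
    if params.rpm_aggregation == "mean":
        return mean_rpm(table, mature_id)
    return pooled_rpm(table, mature_id)


def _mature_rpm(
    table: ExpressionTable,
    mature_id: str,
    params: ScoringParams,
    matures_by_id: Optional[Mapping[str, MatureRecord]] = None,
) -> float:
    """RPM for a mature, resolving accession to name (count tables may use either)."""
    keys = [mature_id]
    if matures_by_id is not None and mature_id in matures_by_id:
        keys.insert(0, matures_by_id[mature_id].name)
    for key in keys:
        if key in table.counts.index:
            return aggregate_rpm(table, key, params)
    return aggregate_rpm(table, keys[0], params)


# ---------------------------------------------------------------------------
# Precursor-level scoring and classification
# ---------------------------------------------------------------------------


def score_precursor(
    precursor: PrecursorRecord,
    pubmed_map: PubmedMap,
    orthology: Mapping[str, set[str]],
    expression_table: ExpressionTable,
    params: ScoringParams = DEFAULT_PARAMS,
    matures_by_id: Optional[Mapping[str, MatureRecord]] = None,
) -> CriterionScores:
    """All four criterion scores for one precursor.

    PubMed counting and the High Confidence flag are precursor-level;
    conservation and expression are taken as the maximum over the precursor's
    mature arms.  ``matures_by_id`` lets expression lookups fall back from
    mature accessions to mature names (count tables may be keyed by either).
    """
    if not precursor.mature_ids:
        raise ValidationError(f"precursor {precursor.name} has no mature arms")
    n_pmids = pubmed_map.n_records(precursor.name, precursor.id)
    n_species = max(len(orthology.get(mid, ())) for mid in precursor.mature_ids)
    rpm = max(
        _mature_rpm(expression_table, mid, params, matures_by_id)
        for mid in precursor.mature_ids
    )
    return CriterionScores(
        pubmed=pubmed_score(n_pmids, params),
        conservation=conservation_score(n_species, params),
        expression=expression_score(rpm, params),
        mirbase=mirbase_score(precursor.high_confidence),
    )


def classify_functional(
    scores: CriterionScores, params: ScoringParams = DEFAULT_PARAMS
) -> bool:
    """Functional iff the composite score reaches the threshold (default 3)."""
    return scores.composite >= params.functional_threshold


def select_functional_matures(
    precursor: PrecursorRecord,
    arm_rpm: Mapping[str, float],
    params: ScoringParams = DEFAULT_PARAMS,
    matures_by_id: Optional[Mapping[str, MatureRecord]] = None,
) -> tuple[str, Optional[str]]:
    """Dominant (and possibly secondary) mature arm of a precursor.

    The dominant arm has the highest RPM (ties prefer the 5p arm, then the
    lexicographically smaller ID).  A secondary arm is selected iff its RPM is
    no less than ``secondary_fraction`` of the dominant arm's AND no less than
    ``secondary_min_rpm``.
    """
    if not precursor.mature_ids:
        raise ValidationError(f"precursor {precursor.name} has no mature arms")

    def sort_key(mid: str):
        arm_rank = 1
        if matures_by_id is not None and mid in matures_by_id:
            arm_rank = 0 if matures_by_id[mid].arm == Arm.FIVE_P else 1
        return (-arm_rpm.get(mid, 0.0), arm_rank, mid)

    ordered = sorted(precursor.mature_ids, key=sort_key)
    dominant = ordered[0]
    secondary: Optional[str] = None
    if len(ordered) > 1:
        runner_up = ordered[1]
        rpm_d = arm_rpm.get(dominant, 0.0)
        rpm_s = arm_rpm.get(runner_up, 0.0)
        if rpm_s >= params.secondary_fraction * rpm_d and rpm_s >= params.secondary_min_rpm:
            secondary = runner_up
    return dominant, secondary


def required_criteria(
    scores: CriterionScores, params: ScoringParams = DEFAULT_PARAMS
) -> frozenset[str]:
    """Criteria whose removal would drop a functional call below threshold.

    A criterion is *required* iff the composite reaches the threshold but the
    composite minus that criterion's score does not.  Non-functional
    precursors have no required criteria by convention.
    """
    if scores.composite < params.functional_threshold:
        return frozenset()
    return frozenset(
        c
        for c in CRITERIA
        if scores.composite - getattr(scores, c) < params.functional_threshold
    )


def n_supporting_criteria(scores: CriterionScores) -> int:
    """Number of criteria with a strictly positive score."""
    return sum(getattr(scores, c) > 0 for c in CRITERIA)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def annotate(
    precursors: Sequence[PrecursorRecord],
    matures: Sequence[MatureRecord],
    pubmed_map: PubmedMap,
    expression_table: ExpressionTable,
    highconf_ids: Iterable[str] = (),
    params: ScoringParams = DEFAULT_PARAMS,
) -> list[FunctionalCall]:
    """Score and classify every precursor; one FunctionalCall per precursor.

    Precursors and matures are expected unlinked or linked; linking and
    high-confidence flagging are (re)applied here so the call is
    self-contained.  A secondary mature is reported only for functional
    precursors.
    """
    from .mirbase_io import apply_high_confidence, link_matures

    highconf = set(highconf_ids)
    if highconf:
        apply_high_confidence(precursors, highconf)
    if any(not p.mature_ids for p in precursors):
        link_matures(precursors, matures)
    matures_by_id = {m.id: m for m in matures}
    orthology = build_orthology_map(matures, params)

    calls: list[FunctionalCall] = []
    for prec in precursors:
        scores = score_precursor(
            prec, pubmed_map, orthology, expression_table, params, matures_by_id
        )
        functional = classify_functional(scores, params)
        rpm_by_arm = {
            mid: _mature_rpm(expression_table, mid, params, matures_by_id)
            for mid in prec.mature_ids
        }
        dominant, secondary = select_functional_matures(
            prec, rpm_by_arm, params, matures_by_id
        )
        if not functional:
            secondary = None
        calls.append(
            FunctionalCall(
                precursor_id=prec.id,
                scores=scores,
                is_functional=functional,
                dominant_mature_id=dominant,
                secondary_mature_id=secondary,
                n_supporting_criteria=n_supporting_criteria(scores),
                required_criteria=required_criteria(scores, params),
            )
        )
    return calls


ANNOTATE_COLUMNS = [
    "precursor_id",
    "name",
    "species",
    "pubmed_score",
    "conservation_score",
    "expression_score",
    "mirbase_score",
    "composite",
    "is_functional",
    "dominant_mature",
    "secondary_mature",
    "n_supporting_criteria",
    "required_criteria",
]


def calls_to_rows(
    calls: Sequence[FunctionalCall],
    precursors: Sequence[PrecursorRecord],
    matures: Sequence[MatureRecord],
) -> list[dict[str, object]]:
    """Flatten FunctionalCalls into result-table rows (mature names, not IDs)."""
    prec_by_id = {p.id: p for p in precursors}
    name_of = {m.id: m.name for m in matures}
    rows = []
    for call in calls:
        prec = prec_by_id[call.precursor_id]
        rows.append(
            {
                "precursor_id": call.precursor_id,
                "name": prec.name,
                "species": prec.species,
                "pubmed_score": call.scores.pubmed,
                "conservation_score": call.scores.conservation,
                "expression_score": call.scores.expression,
                "mirbase_score": call.scores.mirbase,
                "composite": call.scores.composite,
                "is_functional": call.is_functional,
                "dominant_mature": name_of.get(
                    call.dominant_mature_id, call.dominant_mature_id
                ),
                "secondary_mature": name_of.get(call.secondary_mature_id, "")
                if call.secondary_mature_id
                else "",
                "n_supporting_criteria": call.n_supporting_criteria,
                "required_criteria": ";".join(sorted(call.required_criteria)),
            }
        )
    return rows


def params_with_overrides(params: ScoringParams, **overrides) -> ScoringParams:
    """Return a copy of ``params`` with the given fields replaced."""
    return replace(params, **overrides)
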