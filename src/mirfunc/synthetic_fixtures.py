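"""Seeded synthetic fixtures emulating every input the pipeline consumes.

The generator writes a complete, self-consistent file set — multi-species
mature/hairpin FASTA with planted orthologous families (shared 5' 19-mers,
divergent 3' ends), an overdispersed negative-binomial read-count matrix with
stated library sizes, a sparse zero-inflated PubMed association map, a
high-confidence ID list, and 3'-UTR FASTA with planted seed-complementary
sites at recorded coordinates — together with ground-truth labels.

Ground-truth criterion scores are computed by :func:`oracle_scores`, a
deliberately independent straight-line restatement of the scoring rules that
re-parses the written files with plain string code and shares no logic with
:mod:`mirfunc.funcmir`.  It exists so the pipeline can be checked against an
implementation that cannot share its bugs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FixtureSpecError
from .mirbase_io import (
    Arm,
    ExpressionTable,
    MatureRecord,
    PrecursorRecord,
    PubmedMap,
    SPECIES_CODES,
    UtrRecord,
    write_expression_table,
    write_hairpin_fasta,
    write_highconf_list,
    write_mature_fasta,
    write_pubmed_map,
    write_utr_fasta,
)

_NT = "ACGU"
_COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}


@dataclass(frozen=True)
class FixtureSpec:
    """Generator conditions.

    Defaults emulate the study setting: five species, 81 small-RNA-seq
    experiments, per-arm mean abundances spanning the expression brackets,
    sparse literature evidence, and a minority of high-confidence entries.
    """

    rng_seed: int = 0
    n_families: int = 40
    species: tuple[str, ...] = SPECIES_CODES
    #: Probability a family is shared (19-nt 5' identity) across >=2 species;
    #: roughly one miRBase precursor in five has a detectable ortholog.
    ortholog_fraction: float = 0.2
    #: Species-count range for shared families; None means (2, len(species)).
    family_species_range: Optional[tuple[int, int]] = None
    #: Probability a precursor expresses both arms (else 5p only).
    two_arm_fraction: float = 0.75
    #: Per-arm mean abundance drawn log-uniformly from this RPM range;
    #: spans all expression brackets, skewed toward low abundance.
    mean_rpm_range: tuple[float, float] = (0.01, 30.0)
    #: Negative-binomial dispersion (shape); counts ~ NB(mean, size=dispersion).
    nb_dispersion: float = 5.0
    n_experiments: int = 81
    library_size_range: tuple[int, int] = (500_000, 2_000_000)
    #: Probability a precursor has no literature record at all.
    pubmed_zero_fraction: float = 0.55
    #: Positive literature counts are 1 + Poisson(this mean).
    pubmed_mean_extra: float = 1.5
    #: Fraction flagged high-confidence (miRBase flags ~15% of human entries).
    highconf_fraction: float = 0.15
    utr_count: int = 25
    utr_len_range: tuple[int, int] = (300, 3000)
    planted_sites_per_utr: int = 2

    def validate(self) -> None:
        for name in (
            "ortholog_fraction",
            "two_arm_fraction",
            "pubmed_zero_fraction",
            "highconf_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise FixtureSpecError(f"{name}={value} outside [0, 1]")
        if self.n_families < 1 or self.n_experiments < 1 or self.utr_count < 0:
            raise FixtureSpecError("counts must be positive")
        if len(self.species) < 1 or any(s not in SPECIES_CODES for s in self.species):
            raise FixtureSpecError(f"species must be drawn from {SPECIES_CODES}")
        lo, hi = self.utr_len_range
        if lo < 100 or hi < lo:
            raise FixtureSpecError(
                f"utr_len_range {self.utr_len_range} invalid: targets must be >=100 nt"
            )
        if self.planted_sites_per_utr * 14 > lo:
            raise FixtureSpecError(
                f"{self.planted_sites_per_utr} planted sites do not fit in a "
                f"{lo}-nt UTR with spacing"
            )
        if self.mean_rpm_range[0] <= 0 or self.mean_rpm_range[1] < self.mean_rpm_range[0]:
            raise FixtureSpecError(f"invalid mean_rpm_range {self.mean_rpm_range}")
        if self.family_species_range is not None:
            lo, hi = self.family_species_range
            if not 2 <= lo <= hi <= len(self.species):
                raise FixtureSpecError(
                    f"family_species_range {self.family_species_range} must lie "
                    f"within (2, {len(self.species)})"
                )


@dataclass
class PlantedSite:
    transcript_id: str
    mirna_name: str
    start: int  # 0-based
    end: int  # half-open


@dataclass
class GroundTruth:
    """Oracle-computed labels for a fixture set.

    ``scores``: per precursor name — criterion scores, composite, functional
    flag, selected mature names, supporting/required criteria.
    ``sites``: planted seed-complementary site coordinates (generation
    knowledge; incidental matches elsewhere are possible and expected).
    """

    scores: dict[str, dict] = field(default_factory=dict)
    sites: list[PlantedSite] = field(default_factory=list)


@dataclass
class FixtureSet:
    outdir: Path
    mature_fasta: Path
    hairpin_fasta: Path
    counts_tsv: Path
    pubmed_tsv: Path
    highconf_txt: Path
    utr_fasta: Path
    truth_scores_tsv: Path
    truth_sites_tsv: Path
    truth: GroundTruth


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_NT), size=length))


def _revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate(spec: FixtureSpec, outdir: str | Path) -> FixtureSet:
    """Write the full fixture file set and its ground truth under ``outdir``.

    Deterministic in ``spec.rng_seed``: the same spec yields byte-identical
    files.
    """
    spec.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.rng_seed)

    precursors: list[PrecursorRecord] = []
    matures: list[MatureRecord] = []
    mean_rpm: dict[str, float] = {}
    acc = 1

    for fam in range(spec.n_families):
        fam_tag = f"s{fam + 1:03d}"
        if len(spec.species) >= 2 and rng.random() < spec.ortholog_fraction:
            k_lo, k_hi = spec.family_species_range or (2, len(spec.species))
            k = int(rng.integers(k_lo, k_hi + 1))
            members = sorted(
                rng.choice(len(spec.species), size=k, replace=False).tolist()
            )
        else:
            members = [int(rng.integers(0, len(spec.species)))]
        fam_species = [spec.species[i] for i in members]
        # shared 5' 19-mer of the 5p arm; 3' ends diverge per species
        shared_prefix = _random_seq(rng, 19)
        two_arms = rng.random() < spec.two_arm_fraction
        for sp in fam_species:
            tail_len = int(rng.integers(3, 5))
            seq5 = shared_prefix + _random_seq(rng, tail_len)
            prec_name = f"{sp}-mir-{fam_tag}"
            prec_id = f"MI{acc:07d}"
            arm_records = []
            mat5 = MatureRecord(
                id=f"MIMAT{acc:07d}",
                name=f"{sp}-miR-{fam_tag}-5p",
                species=sp,
                sequence=seq5,
                arm=Arm.FIVE_P,
            )
            arm_records.append(mat5)
            if two_arms:
                seq3 = _random_seq(rng, int(rng.integers(20, 25)))
                arm_records.append(
                    MatureRecord(
                        id=f"MIMAT{acc:07d}b",
                        name=f"{sp}-miR-{fam_tag}-3p",
                        species=sp,
                        sequence=seq3,
                        arm=Arm.THREE_P,
                    )
                )
            loop = _random_seq(rng, 15)
            hairpin_seq = "".join(m.sequence for m in arm_records[:1]) + loop
            if len(arm_records) > 1:
                hairpin_seq += arm_records[1].sequence
            else:
                hairpin_seq += _random_seq(rng, 20)
            historical = [f"{sp}-mir-old-{fam_tag}"] if rng.random() < 0.2 else []
            precursors.append(
                PrecursorRecord(
                    id=prec_id,
                    name=prec_name,
                    species=sp,
                    sequence=hairpin_seq,
                    historical_names=historical,
                )
            )
            for m in arm_records:
                matures.append(m)
                lo, hi = spec.mean_rpm_range
                mean_rpm[m.name] = float(
                    np.exp(rng.uniform(np.log(lo), np.log(hi)))
                )
            acc += 1

    # --- expression counts: NB(mean = rpm * L_j / 1e6, size = dispersion) ---
    experiments = [f"exp{j + 1:02d}" for j in range(spec.n_experiments)]
    lib_sizes = rng.integers(
        spec.library_size_range[0],
        spec.library_size_range[1] + 1,
        size=spec.n_experiments,
    )
    counts = np.zeros((len(matures), spec.n_experiments), dtype=np.int64)
    r = spec.nb_dispersion
    for i, mat in enumerate(matures):
        mu = mean_rpm[mat.name] * lib_sizes / 1e6
        p = r / (r + mu)
        counts[i] = rng.negative_binomial(r, p)
    counts_df = pd.DataFrame(
        counts, index=[m.name for m in matures], columns=experiments
    )
    lib_series = pd.Series(lib_sizes, index=experiments, dtype="int64")
    # stated library sizes dominate the tiny fixture miRNome by construction
    lib_series = pd.concat(
        [lib_series, counts_df.sum(axis=0)], axis=1
    ).max(axis=1).astype("int64")
    table = ExpressionTable(counts=counts_df, library_sizes=lib_series)

    # --- sparse literature evidence (zero-inflated) ---
    associations: dict[str, set[int]] = {}
    for prec in precursors:
        if rng.random() < spec.pubmed_zero_fraction:
            continue
        n = 1 + int(rng.poisson(spec.pubmed_mean_extra))
        pmids = set()
        while len(pmids) < n:
            pmids.add(int(rng.integers(10_000_000, 40_000_000)))
        associations[prec.name] = pmids
    pubmed = PubmedMap(associations=associations)

    highconf = sorted(
        p.name for p in precursors if rng.random() < spec.highconf_fraction
    )

    # --- UTRs with planted seed-complementary sites ---
    scan_species = spec.species[0]
    scan_matures = [m for m in matures if m.species == scan_species]
    utrs: list[UtrRecord] = []
    planted: list[PlantedSite] = []
    for u in range(spec.utr_count):
        length = int(rng.integers(spec.utr_len_range[0], spec.utr_len_range[1] + 1))
        seq = list(_random_seq(rng, length))
        tid = f"NM_{900000 + u}"
        used: list[tuple[int, int]] = []
        for _ in range(spec.planted_sites_per_utr):
            if not scan_matures:
                break
            mat = scan_matures[int(rng.integers(0, len(scan_matures)))]
            probe = _revcomp(mat.sequence[1:8])  # seed positions 2-8
            for _attempt in range(50):
                start = int(rng.integers(0, length - 7 + 1))
                if all(start + 7 <= a or start >= b for a, b in used):
                    break
            else:
                continue
            seq[start : start + 7] = probe
            used.append((start, start + 7))
            planted.append(
                PlantedSite(
                    transcript_id=tid,
                    mirna_name=mat.name,
                    start=start,
                    end=start + 7,
                )
            )
        utrs.append(
            UtrRecord(
                transcript_id=tid,
                gene_symbol=f"GENE{u + 1}",
                description=f"synthetic 3' UTR {u + 1}",
                species=scan_species,
                sequence="".join(seq),
            )
        )
    planted.sort(key=lambda s: (s.transcript_id, s.start, s.mirna_name))

    # --- write the file set in the dialects mirbase_io reads ---
    paths = FixtureSet(
        outdir=outdir,
        mature_fasta=outdir / "mature.fa",
        hairpin_fasta=outdir / "hairpin.fa",
        counts_tsv=outdir / "counts.tsv",
        pubmed_tsv=outdir / "mirna2pubmed.tsv",
        highconf_txt=outdir / "high_confidence.txt",
        utr_fasta=outdir / "utr.fa",
        truth_scores_tsv=outdir / "truth_scores.tsv",
        truth_sites_tsv=outdir / "truth_sites.tsv",
        truth=GroundTruth(),
    )
    write_mature_fasta(matures, paths.mature_fasta)
    write_hairpin_fasta(precursors, paths.hairpin_fasta)
    write_expression_table(table, paths.counts_tsv)
    write_pubmed_map(pubmed, paths.pubmed_tsv)
    write_highconf_list(highconf, paths.highconf_txt)
    write_utr_fasta(utrs, paths.utr_fasta)

    truth = oracle_scores(paths)
    truth.sites = planted
    paths.truth = truth
    _write_truth(truth, paths.truth_scores_tsv, paths.truth_sites_tsv)
    return paths


def _write_truth(truth: GroundTruth, scores_path: Path, sites_path: Path) -> None:
    score_cols = [
        "precursor",
        "pubmed",
        "conservation",
        "expression",
        "mirbase",
        "composite",
        "functional",
        "dominant_mature",
        "secondary_mature",
        "n_supporting",
        "required",
    ]
    with open(scores_path, "w") as fh:
        fh.write("\t".join(score_cols) + "\n")
        for name in sorted(truth.scores):
            s = truth.scores[name]
            fh.write(
                "\t".join(
                    str(s[c]) if c != "precursor" else name for c in score_cols
                )
                + "\n"
            )
    with open(sites_path, "w") as fh:
        fh.write("transcript_id\tmirna_name\tstart\tend\n")
        for site in truth.sites:
            fh.write(
                f"{site.transcript_id}\t{site.mirna_name}\t{site.start}\t{site.end}\n"
            )


# ---------------------------------------------------------------------------
# Independent scoring oracle
# ---------------------------------------------------------------------------
# Everything below re-reads the files with straight-line string code and
# applies the published bracket sentences literally.  It must share no code
# with mirfunc.funcmir or mirfunc.mirbase_io.


def _oracle_read_fasta(path: Path) -> list[tuple[str, str]]:
    entries: list[tuple[str, str]] = []
    header = None
    chunks: list[str] = []
    for line in open(path):
        line = line.rstrip("\n")
        if line.startswith(">"):
            if header is not None:
                entries.append((header, "".join(chunks)))
            header = line[1:]
            chunks = []
        elif line:
            chunks.append(line.strip().upper().replace("T", "U"))
    if header is not None:
        entries.append((header, "".join(chunks)))
    return entries


def oracle_scores(paths: "FixtureSet") -> GroundTruth:
    """Recompute every ground-truth label by literal application of the rules."""
    matures = []  # (name, species, sequence)
    for header, seq in _oracle_read_fasta(paths.mature_fasta):
        name = header.split()[0]
        matures.append((name, name.split("-")[0], seq))
    precursors = []  # (name, species)
    for header, _seq in _oracle_read_fasta(paths.hairpin_fasta):
        name = header.split()[0]
        precursors.append((name, name.split("-")[0]))

    # counts table
    lines = open(paths.counts_tsv).read().splitlines()
    experiments = lines[0].split("\t")[1:]
    counts: dict[str, list[int]] = {}
    lib_sizes: list[int] = []
    for line in lines[1:]:
        cells = line.split("\t")
        if cells[0] == "library_size":
            lib_sizes = [int(c) for c in cells[1:]]
        else:
            counts[cells[0]] = [int(c) for c in cells[1:]]
    total_lib = sum(lib_sizes) if lib_sizes else sum(
        sum(v[j] for v in counts.values()) for j in range(len(experiments))
    )

    # pubmed map
    pmids: dict[str, set[int]] = {}
    for line in open(paths.pubmed_tsv):
        line = line.strip()
        if line:
            key, pmid = line.split("\t")
            pmids.setdefault(key, set()).add(int(pmid))

    highconf = {l.strip() for l in open(paths.highconf_txt) if l.strip()}

    def rpm_of(mature_name: str) -> float:
        row = counts.get(mature_name)
        if row is None or total_lib == 0:
            return 0.0
        return 1e6 * sum(row) / total_lib

    def ortholog_species(name: str, species: str, seq: str) -> set[str]:
        found = set()
        for other_name, other_sp, other_seq in matures:
            if other_sp == species:
                continue
            k = min(19, len(seq), len(other_seq))
            if seq[:k] == other_seq[:k]:
                found.add(other_sp)
        return found

    # group matures by precursor: strip -5p/-3p, compare case-insensitively
    arms_of: dict[str, list[tuple[str, str, str]]] = {}
    for name, sp, seq in matures:
        stem = name.lower()
        for suffix in ("-5p", "-3p"):
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
        arms_of.setdefault(stem, []).append((name, sp, seq))

    truth = GroundTruth()
    for prec_name, prec_sp in precursors:
        arms = arms_of.get(prec_name.lower(), [])
        if not arms:
            continue

        n_pub = len(pmids.get(prec_name, set()))
        if n_pub >= 4:
            s_pub = 3
        elif n_pub == 3:
            s_pub = 2
        elif n_pub == 2:
            s_pub = 1
        else:
            s_pub = 0

        n_orth = max(len(ortholog_species(n, sp, sq)) for n, sp, sq in arms)
        if n_orth >= 2:
            s_cons = 2
        elif n_orth == 1:
            s_cons = 1
        else:
            s_cons = 0

        best_rpm = max(rpm_of(n) for n, _, _ in arms)
        if best_rpm > 10:
            s_expr = 2
        elif best_rpm >= 1:
            s_expr = 1
        else:
            s_expr = 0

        s_base = 1 if prec_name in highconf else 0

        composite = s_pub + s_cons + s_expr + s_base
        functional = composite >= 3

        # dominant arm: highest RPM; ties prefer the 5p arm, then name order
        def arm_key(arm):
            name = arm[0]
            return (-rpm_of(name), 0 if name.lower().endswith("-5p") else 1, name)

        ordered = sorted(arms, key=arm_key)
        dominant = ordered[0][0]
        secondary = ""
        if functional and len(ordered) > 1:
            cand = ordered[1][0]
            if (
                rpm_of(cand) >= 0.10 * rpm_of(dominant)
                and rpm_of(cand) >= 5.0
            ):
                secondary = cand

        required = []
        if functional:
            for label, s in (
                ("conservation", s_cons),
                ("expression", s_expr),
                ("mirbase", s_base),
                ("pubmed", s_pub),
            ):
                if composite - s < 3:
                    required.append(label)
        truth.scores[prec_name] = {
            "pubmed": s_pub,
            "conservation": s_cons,
            "expression": s_expr,
            "mirbase": s_base,
            "composite": composite,
            "functional": functional,
            "dominant_mature": dominant,
            "secondary_mature": secondary,
            "n_supporting": sum(1 for s in (s_pub, s_cons, s_expr, s_base) if s > 0),
            "required": ";".join(sorted(required)),
        }
    return truth


def naive_seed_sites(seed_revcomp: str, target_seq: str) -> list[int]:
    """Brute-force all-window substring oracle; returns 0-based match starts."""
    k = len(seed_revcomp)
    return [
        i
        for i in range(len(target_seq) - k + 1)
        if target_seq[i : i + k] == seed_revcomp
    ]


def load_fixture_set(outdir: str | Path) -> FixtureSet:
    """Paths object for an existing fixture directory (truth not loaded)."""
    outdir = Path(outdir)
    return FixtureSet(
        outdir=outdir,
        mature_fasta=outdir / "mature.fa",
        hairpin_fasta=outdir / "hairpin.fa",
        counts_tsv=outdir / "counts.tsv",
        pubmed_tsv=outdir / "mirna2pubmed.tsv",
        highconf_txt=outdir / "high_confidence.txt",
        utr_fasta=outdir / "utr.fa",
        truth_scores_tsv=outdir / "truth_scores.tsv",
        truth_sites_tsv=outdir / "truth_sites.tsv",
        truth=GroundTruth(),
    )
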