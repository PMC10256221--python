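"""Empirical-data plumbing: reference, annotation, SNV typing, haplotype tables.

The sequencing side of the pipeline works on *haplotype tables* — one row per
full-length read carrying the read's SNV list against the reference
(positions are 1-based; SNV identifiers follow the ``A1697C`` convention:
reference base, position, alternative base).  This module reads and writes
those tables, applies the read-filtering policy, classifies SNVs as
synonymous or non-synonymous against a CDS annotation with overlapping
reading frames (a substitution silent in one gene but missense in an
overlapping gene counts as non-synonymous), converts labeled tables to
genotype-class distributions, and generates fully synthetic fixture tables
from the simulator for testing and validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio import SeqIO

from .model import (
    ClassDistribution, ExperimentConfig, ModelParams, simulate_experiment,
)

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
STOP_AA = "*"


# ---------------------------------------------------------------------------
# reference + annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CDS:
    """A coding region: 1-based inclusive coordinates, frame offset in bases."""

    name: str
    start: int
    end: int
    frame: int = 0


@dataclass
class ReferenceAnnotation:
    """Genome sequence plus CDS intervals (overlapping genes allowed)."""

    sequence: str
    cds: list

    def __post_init__(self):
        self.sequence = self.sequence.upper().replace("U", "T")
        if set(self.sequence) - set(BASES):
            raise ValueError("sequence contains non-ACGT(U) characters")
        for c in self.cds:
            if not (1 <= c.start <= c.end <= len(self.sequence)):
                raise ValueError(f"CDS {c.name} outside the genome")
            if (c.end - (c.start + c.frame) + 1) % 3 != 0:
                raise ValueError(f"CDS {c.name} length not divisible by 3 in its frame")

    @property
    def genome_length(self) -> int:
        return len(self.sequence)

    def coding_positions(self) -> np.ndarray:
        mask = np.zeros(self.genome_length + 1, dtype=bool)
        for c in self.cds:
            mask[c.start + c.frame: c.end + 1] = True
        return np.nonzero(mask)[0]

    @classmethod
    def from_files(cls, fasta_path, cds_path) -> "ReferenceAnnotation":
        record = next(SeqIO.parse(str(fasta_path), "fasta"))
        cds_df = pd.read_csv(cds_path, sep="\t")
        cds = [CDS(str(r.gene), int(r.start), int(r.end), int(r.frame))
               for r in cds_df.itertuples()]
        return cls(str(record.seq), cds)

    def to_files(self, fasta_path, cds_path, name: str = "reference") -> None:
        with open(fasta_path, "w") as fh:
            fh.write(f">{name}\n")
            for i in range(0, len(self.sequence), 70):
                fh.write(self.sequence[i:i + 70] + "\n")
        pd.DataFrame(
            [{"seqid": name, "start": c.start, "end": c.end,
              "frame": c.frame, "gene": c.name} for c in self.cds]
        ).to_csv(cds_path, sep="\t", index=False)


def classify_snv(position: int, ref: str, alt: str, annotation: ReferenceAnnotation) -> str:
    """Classify a substitution as synonymous / non-synonymous / non-coding.

    The substitution is evaluated in every CDS whose reading frame covers the
    position: amino-acid-changing in any frame means non-synonymous; silent in
    all covering frames means synonymous; covered by no frame means
    non-coding.
    """
    seq = annotation.sequence
    if not (1 <= position <= len(seq)):
        raise ValueError(f"position {position} outside genome of length {len(seq)}")
    ref, alt = ref.upper().replace("U", "T"), alt.upper().replace("U", "T")
    if seq[position - 1] != ref:
        raise ValueError(
            f"reference base at {position} is {seq[position - 1]}, not {ref}")
    coding = False
    for c in annotation.cds:
        cds_start = c.start + c.frame
        if not (cds_start <= position <= c.end):
            continue
        offset = (position - cds_start) % 3
        codon_start = position - offset
        if codon_start + 2 > c.end:
            continue  # incomplete trailing codon
        coding = True
        codon = seq[codon_start - 1: codon_start + 2]
        mutated = codon[:offset] + alt + codon[offset + 1:]
        if Seq(codon).translate() != Seq(mutated).translate():
            return "non-synonymous"
    return "synonymous" if coding else "non-coding"


def compute_ps(annotation: ReferenceAnnotation) -> float:
    """Fraction of possible coding point substitutions that are synonymous.

    Enumerates all three substitutions at every coding site and classifies
    each; the result is the model's p_s.
    """
    if not annotation.cds:
        raise ValueError("annotation has no CDS")
    seq = annotation.sequence
    n_syn = n_total = 0
    for pos in annotation.coding_positions():
        ref = seq[pos - 1]
        for alt in BASES:
            if alt == ref:
                continue
            kind = classify_snv(int(pos), ref, alt, annotation)
            if kind == "non-coding":
                continue
            n_total += 1
            n_syn += kind == "synonymous"
    if n_total == 0:
        raise ValueError("no classifiable coding substitutions")
    return n_syn / n_total


def possible_stop_snvs(annotation: ReferenceAnnotation) -> list:
    """All (position, ref, alt) whose substitution creates a premature stop.

    A substitution counts if it turns a non-terminal, non-stop codon of any
    CDS into a stop codon.
    """
    seq = annotation.sequence
    out = set()
    for c in annotation.cds:
        cds_start = c.start + c.frame
        n_codons = (c.end - cds_start + 1) // 3
        for ci in range(n_codons - 1):  # exclude the terminal codon
            codon_start = cds_start + 3 * ci
            codon = seq[codon_start - 1: codon_start + 2]
            if Seq(codon).translate() == STOP_AA:
                continue
            for offset in range(3):
                ref = codon[offset]
                for alt in BASES:
                    if alt == ref:
                        continue
                    mutated = codon[:offset] + alt + codon[offset + 1:]
                    if Seq(mutated).translate() == STOP_AA:
                        out.add((codon_start + offset, ref, alt))
    return sorted(out)


# ---------------------------------------------------------------------------
# SNV identifiers and haplotype tables
# ---------------------------------------------------------------------------

def format_snv(position: int, ref: str, alt: str) -> str:
    return f"{ref}{position}{alt}"


def parse_snv(token: str) -> tuple[int, str, str]:
    token = token.strip()
    if len(token) < 3 or token[0] not in BASES + ("U",) or token[-1] not in BASES + ("U",):
        raise ValueError(f"malformed SNV token {token!r}")
    return int(token[1:-1]), token[0], token[-1]


TABLE_COLUMNS = ("read_id", "line", "passage", "snvs")


def write_haplotype_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, columns=list(TABLE_COLUMNS))


def read_haplotype_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snvs": str})
    df["snvs"] = df["snvs"].fillna("")
    return df


def snv_trajectories(table: pd.DataFrame) -> pd.DataFrame:
    """Per-line, per-passage SNV frequencies from a haplotype table."""
    rows = []
    for (line, passage), group in table.groupby(["line", "passage"]):
        n = len(group)
        counts: dict = {}
        for s in group["snvs"]:
            if not s:
                continue
            for tok in str(s).split(";"):
                counts[tok] = counts.get(tok, 0) + 1
        for snv, c in counts.items():
            rows.append({"line": line, "passage": passage,
                         "snv": snv, "frequency": c / n})
    return pd.DataFrame(rows, columns=["line", "passage", "snv", "frequency"])


def identify_founder_snvs(
    trajectories: pd.DataFrame, first_passage: int = 3, threshold: float = 0.05,
) -> set:
    """SNVs already common at the first sequenced passage (standing variation)."""
    if trajectories.empty:
        return set()
    early = trajectories[trajectories["passage"] == first_passage]
    grp = early.groupby("snv")["frequency"].min()
    return set(grp[grp > threshold].index)


# ---------------------------------------------------------------------------
# read filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadFilterPolicy:
    """Gates applied to long-read alignment records before analysis."""

    min_aligned_fraction: float = 0.98
    unique_alignment_required: bool = True
    plus_strand_only: bool = True
    exclude_indels: bool = True

    def __post_init__(self):
        if not (0 < self.min_aligned_fraction <= 1):
            raise ValueError("min_aligned_fraction must be in (0, 1]")


def filter_reads(
    alignments: pd.DataFrame,
    policy: ReadFilterPolicy,
    annotation: ReferenceAnnotation,
) -> tuple[pd.DataFrame, dict]:
    """Apply the filter policy to alignment records.

    ``alignments`` needs columns read_id, line, passage, aligned_length,
    strand ('+'/'-'), n_alignments, snvs (semicolon-joined tokens, possibly
    with indel tokens containing '-').  Returns the retained haplotype table
    and a report of rejection counts per reason.
    """
    min_len = policy.min_aligned_fraction * annotation.genome_length
    report = {"retained": 0, "too_short": 0, "multiple_alignments": 0,
              "minus_strand": 0, "malformed": 0}
    rows = []
    for rec in alignments.itertuples():
        try:
            length = int(rec.aligned_length)
            n_aln = int(rec.n_alignments)
            strand = str(rec.strand)
            snvs = "" if pd.isna(rec.snvs) else str(rec.snvs)
        except (ValueError, AttributeError, TypeError) as exc:
            logger.warning("skipping malformed alignment record: %s", exc)
            report["malformed"] += 1
            continue
        if policy.unique_alignment_required and n_aln != 1:
            report["multiple_alignments"] += 1
            continue
        if length < min_len:
            report["too_short"] += 1
            continue
        if policy.plus_strand_only and strand != "+":
            report["minus_strand"] += 1
            continue
        tokens = []
        ok = True
        for tok in filter(None, snvs.split(";")):
            if "-" in tok:          # indel token
                if policy.exclude_indels:
                    continue
                tokens.append(tok)
                continue
            try:
                parse_snv(tok)
            except ValueError:
                logger.warning("read %s has malformed SNV %r; skipping read",
                               rec.read_id, tok)
                ok = False
                break
            tokens.append(tok)
        if not ok:
            report["malformed"] += 1
            continue
        rows.append({"read_id": rec.read_id, "line": rec.line,
                     "passage": rec.passage, "snvs": ";".join(tokens)})
        report["retained"] += 1
    return pd.DataFrame(rows, columns=list(TABLE_COLUMNS)), report


# ---------------------------------------------------------------------------
# table -> genotype classes
# ---------------------------------------------------------------------------

def table_to_class_distribution(
    table: pd.DataFrame,
    annotation: ReferenceAnnotation,
    beneficial: set,
    founder: set,
) -> dict:
    """Map reads to genotype classes; returns {(line, passage): ClassDistribution}.

    Every SNV must classify as synonymous or non-synonymous (non-coding SNVs
    should have been excluded by the filter policy and raise an error here).
    The class tuple is (founder-syn, founder-nonsyn, de-novo syn, de-novo
    nonsyn, beneficial-syn, beneficial-nonsyn).
    """
    kind_cache: dict = {}

    def snv_kind(tok: str) -> str:
        if tok not in kind_cache:
            pos, ref, alt = parse_snv(tok)
            kind = classify_snv(pos, ref, alt, annotation)
            if kind == "non-coding":
                raise ValueError(f"SNV {tok} is non-coding; cannot assign a class")
            kind_cache[tok] = kind
        return kind_cache[tok]

    out = {}
    for (line, passage), group in table.groupby(["line", "passage"]):
        counts: dict = {}
        for s in group["snvs"]:
            k = [0, 0, 0, 0, 0, 0]
            for tok in filter(None, str(s).split(";") if not pd.isna(s) else []):
                syn = snv_kind(tok) == "synonymous"
                if tok in founder:
                    k[0 if syn else 1] += 1
                elif tok in beneficial:
                    k[4 if syn else 5] += 1
                else:
                    k[2 if syn else 3] += 1
            key = tuple(k)
            counts[key] = counts.get(key, 0) + 1
        n = sum(counts.values())
        out[(line, passage)] = ClassDistribution.from_dict(
            {k: c / n for k, c in counts.items()})
    return out


# ---------------------------------------------------------------------------
# synthetic toy genome + fixture generator
# ---------------------------------------------------------------------------

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_SAFE_CODONS = ["".join((a, b, c)) for a in BASES for b in BASES for c in BASES
                if "".join((a, b, c)) not in _STOP_CODONS]


def make_toy_annotation(seed: int = 0, n_codons_gene1: int = 200) -> ReferenceAnnotation:
    """A synthetic genome with two CDSs, one overlapping the other out of frame.

    Layout (1-based): a 60-nt 5' UTR, gene1 of ``n_codons_gene1`` codons
    (terminal stop included), gene2 starting one base into gene1's last
    20 codons (so the two reading frames overlap, like the coat/lysis pair),
    and a short 3' UTR.  Internal stop codons are avoided in both frames.
    Entirely synthetic — generated from ``seed``, no relation to any real
    genome.
    """
    rng = np.random.default_rng(seed)
    utr5 = 60
    g1_start = utr5 + 1
    g1_end = g1_start + 3 * n_codons_gene1 - 1
    g2_start = g1_end - 58          # one base offset from gene1's frame
    g2_end = g2_start + 239
    utr3 = 59
    length = g2_end + utr3

    def rand_seq(n):
        return "".join(rng.choice(BASES, size=n))

    def rand_codon():
        return _SAFE_CODONS[rng.integers(0, len(_SAFE_CODONS))]

    genome = list(rand_seq(length))
    # gene1: internal codons stop-free, terminal TAA
    for ci in range(n_codons_gene1 - 1):
        genome[g1_start - 1 + 3 * ci: g1_start + 2 + 3 * ci] = rand_codon()
    genome[g1_end - 3: g1_end] = "TAA"
    # gene2 tail beyond gene1: stop-free codons, terminal TAA
    n_codons_g2 = 80
    for ci in range(n_codons_g2 - 1):
        cs = g2_start + 3 * ci
        if cs > g1_end:  # fully outside gene1: free to place a safe codon
            genome[cs - 1: cs + 2] = rand_codon()
    genome[g2_end - 3: g2_end] = "TAA"
    # repair: remove stops that gene1 imposed on gene2's overlapping codons
    for _ in range(1000):
        bad = None
        for ci in range(n_codons_g2 - 1):
            cs = g2_start + 3 * ci
            if "".join(genome[cs - 1: cs + 2]) in _STOP_CODONS:
                bad = cs
                break
        if bad is None:
            break
        # resample the gene1 codons covering positions bad..bad+2
        for pos in range(bad, bad + 3):
            if g1_start <= pos <= g1_end - 3:
                ci1 = (pos - g1_start) // 3
                cs1 = g1_start + 3 * ci1
                genome[cs1 - 1: cs1 + 2] = rand_codon()
            elif pos > g1_end:
                genome[pos - 1] = str(rng.choice(BASES))
    else:  # pragma: no cover
        raise RuntimeError("could not build a stop-free overlapping gene pair")
    return ReferenceAnnotation(
        "".join(genome),
        [CDS("gene1", g1_start, g1_end), CDS("gene2", g2_start, g2_end)],
    )


@dataclass
class FixtureGroundTruth:
    """What the synthetic fixture generator actually used."""

    params: ModelParams
    config: ExperimentConfig
    annotation: ReferenceAnnotation
    founder_snvs: set
    beneficial_snvs: set
    seed: int
    class_distributions: dict = field(default_factory=dict)  # (line, passage) -> ClassDistribution


def _snv_pools(annotation: ReferenceAnnotation, rng) -> dict:
    """Disjoint site-allele pools per SNV role, sampled from the genome."""
    syn, nonsyn = [], []
    seq = annotation.sequence
    for pos in annotation.coding_positions():
        ref = seq[pos - 1]
        for alt in BASES:
            if alt == ref:
                continue
            kind = classify_snv(int(pos), ref, alt, annotation)
            if kind == "synonymous":
                syn.append((int(pos), ref, alt))
            elif kind == "non-synonymous":
                nonsyn.append((int(pos), ref, alt))
    syn_idx = rng.permutation(len(syn))
    ns_idx = rng.permutation(len(nonsyn))
    syn = [syn[i] for i in syn_idx]
    nonsyn = [nonsyn[i] for i in ns_idx]
    return {
        "founder_syn": syn[:30], "beneficial_syn": syn[30:45], "denovo_syn": syn[45:],
        "founder_nonsyn": nonsyn[:30], "beneficial_nonsyn": nonsyn[30:45],
        "denovo_nonsyn": nonsyn[45:],
    }


_POOL_BY_COMPONENT = ("founder_syn", "founder_nonsyn", "denovo_syn",
                      "denovo_nonsyn", "beneficial_syn", "beneficial_nonsyn")


def generate_fixture(
    params: ModelParams,
    config: ExperimentConfig,
    n_lines: int = 3,
    seed: int = 0,
    annotation: ReferenceAnnotation | None = None,
) -> tuple[pd.DataFrame, FixtureGroundTruth]:
    """Simulate an experiment and materialize it as a haplotype table.

    Runs the genotype-class simulator once per line, then realizes every
    sequenced read by assigning concrete genome positions and alleles
    consistent with its class: founder SNVs come from a designated founder
    pool, beneficial SNVs from a beneficial pool, de-novo SNVs from the rest,
    each classified against the annotation so the synonymous/non-synonymous
    labels hold by construction.  Round-trips through
    :func:`table_to_class_distribution` to exactly the simulated class
    frequencies.
    """
    annotation = annotation or make_toy_annotation()
    ss = np.random.SeedSequence(seed)
    pool_seed, *line_seeds = ss.spawn(2 * n_lines + 1)
    rng = np.random.default_rng(pool_seed)
    pools = _snv_pools(annotation, rng)
    lines = [chr(ord("A") + i) for i in range(n_lines)]
    truth = FixtureGroundTruth(
        params=params, config=config, annotation=annotation,
        founder_snvs={format_snv(*s) for s in pools["founder_syn"] + pools["founder_nonsyn"]},
        beneficial_snvs={format_snv(*s)
                         for s in pools["beneficial_syn"] + pools["beneficial_nonsyn"]},
        seed=seed,
    )
    rows = []
    for li, line in enumerate(lines):
        sim = simulate_experiment(params, config, line_seeds[li])
        read_rng = np.random.default_rng(line_seeds[n_lines + li])
        for passage in sorted(sim.observed):
            dist = sim.observed[passage]
            truth.class_distributions[(line, passage)] = dist
            n_s = config.coverage_at(passage)
            counts = np.rint(dist.freq * n_s).astype(int)
            r = 0
            for k, c in zip(dist.classes.tolist(), counts):
                for _ in range(c):
                    snvs = _materialize_read(k, pools, read_rng)
                    rows.append({
                        "read_id": f"{line}_p{passage}_{r:05d}", "line": line,
                        "passage": passage,
                        "snvs": ";".join(format_snv(*s) for s in snvs),
                    })
                    r += 1
    table = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    return table, truth


def _materialize_read(k, pools: dict, rng) -> list:
    """Pick concrete SNVs for a class tuple; positions unique within the read."""
    for _ in range(100):
        snvs, positions = [], set()
        ok = True
        for count, pool_name in zip(k, _POOL_BY_COMPONENT):
            pool = pools[pool_name]
            if count > len(pool):
                raise ValueError(
                    f"class component needs {count} SNVs but pool {pool_name} "
                    f"has only {len(pool)}")
            picks = rng.choice(len(pool), size=count, replace=False)
            for i in picks:
                snv = pool[i]
                if snv[0] in positions:
                    ok = False
                    break
                positions.add(snv[0])
                snvs.append(snv)
            if not ok:
                break
        if ok:
            return sorted(snvs)
    raise RuntimeError("could not place SNVs at unique positions")  # pragma: no cover
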