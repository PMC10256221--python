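"""Haplotype summary statistics of increasing information content.

Three summaries condense a set of per-passage genotype-class distributions:

* **SR** ("short reads"): mean number of synonymous and non-synonymous SNVs
  per genome at each sequenced passage — 2 entries per passage.
* **LR** ("long reads"): the joint spectrum of (synonymous, non-synonymous)
  SNV counts per genome, resolved up to ``cell_cap`` SNVs of each type
  (66 cells for a cap of 10), plus the SR entries — 68 per passage.
* **L-LR** ("labeled long reads"): the spectrum additionally resolved by the
  beneficial label, i.e. 4-tuples (syn non-beneficial, syn beneficial,
  non-syn non-beneficial, non-syn beneficial) with total <= cap
  (1,001 cells for a cap of 10), plus SR — 1,003 per passage.

For three sequenced passages the vectors have 6, 204 and 3,009 entries.
Genomes whose type totals exceed the cap do not enter the frequency cells
(their mass is absent, not clipped); the SR entries still carry their SNVs.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .model import ClassDistribution

DEFAULT_CELL_CAP = 10

SUMMARY_KINDS = ("SR", "LR", "L-LR")


@dataclass
class SummaryVector:
    kind: str
    values: np.ndarray
    layout: list  # per-entry descriptor: (passage, label)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.layout) != self.values.size:
            raise ValueError("layout length must match values length")

    def __len__(self):
        return self.values.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "passage": [p for p, _ in self.layout],
            "cell": [c for _, c in self.layout],
            "value": self.values,
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, kind: str) -> "SummaryVector":
        df = pd.read_csv(path, sep="\t")
        return cls(kind, df["value"].to_numpy(),
                   list(zip(df["passage"], df["cell"])))


@lru_cache(maxsize=None)
def lr_cells(cap: int = DEFAULT_CELL_CAP) -> tuple:
    """Lexicographic (syn, nonsyn) count pairs with syn + nonsyn <= cap."""
    return tuple((s, n) for s in range(cap + 1) for n in range(cap + 1 - s))


@lru_cache(maxsize=None)
def llr_cells(cap: int = DEFAULT_CELL_CAP) -> tuple:
    """Lexicographic 4-tuples (syn-nonben, syn-ben, nonsyn-nonben, nonsyn-ben)
    with total <= cap."""
    return tuple(
        (a, b, c, d)
        for a in range(cap + 1)
        for b in range(cap + 1 - a)
        for c in range(cap + 1 - a - b)
        for d in range(cap + 1 - a - b - c)
    )


def _check_passages(observed: dict, passages) -> list:
    passages = sorted(observed) if passages is None else list(passages)
    missing = [t for t in passages if t not in observed]
    if missing:
        raise ValueError(f"missing sequenced passages: {missing}")
    return passages


def _sr_pair(dist: ClassDistribution) -> tuple[float, float]:
    k = dist.classes
    syn = float(dist.freq @ (k[:, 0] + k[:, 2] + k[:, 4]))
    nonsyn = float(dist.freq @ (k[:, 1] + k[:, 3] + k[:, 5]))
    return syn, nonsyn


def sr_statistic(observed: dict, passages=None) -> SummaryVector:
    """Mean synonymous and non-synonymous SNV count per genome, per passage."""
    passages = _check_passages(observed, passages)
    values, layout = [], []
    for t in passages:
        syn, nonsyn = _sr_pair(observed[t])
        values += [syn, nonsyn]
        layout += [(t, "mean_syn"), (t, "mean_nonsyn")]
    return SummaryVector("SR", values, layout)


def lr_statistic(observed: dict, passages=None, cap: int = DEFAULT_CELL_CAP) -> SummaryVector:
    """SR entries plus the (syn, nonsyn) count-spectrum cells, per passage."""
    passages = _check_passages(observed, passages)
    cells = lr_cells(cap)
    index = {c: i for i, c in enumerate(cells)}
    values, layout = [], []
    for t in passages:
        d = observed[t]
        syn, nonsyn = _sr_pair(d)
        spectrum = np.zeros(len(cells))
        s_tot = d.classes[:, 0] + d.classes[:, 2] + d.classes[:, 4]
        n_tot = d.classes[:, 1] + d.classes[:, 3] + d.classes[:, 5]
        for s, n, f in zip(s_tot, n_tot, d.freq):
            cell = (int(s), int(n))
            if cell in index:  # genomes beyond the cap are excluded
                spectrum[index[cell]] += f
        values += [syn, nonsyn] + list(spectrum)
        layout += [(t, "mean_syn"), (t, "mean_nonsyn")]
        layout += [(t, f"f({s},{n})") for s, n in cells]
    return SummaryVector("LR", values, layout)


def llr_statistic(observed: dict, passages=None, cap: int = DEFAULT_CELL_CAP) -> SummaryVector:
    """SR entries plus the beneficial-label-resolved count spectrum, per passage.

    Simulated distributions carry the beneficial label intrinsically (the
    k_bs / k_bns components); empirical tables acquire it via
    :func:`label_beneficial` before conversion to class distributions.
    """
    passages = _check_passages(observed, passages)
    cells = llr_cells(cap)
    index = {c: i for i, c in enumerate(cells)}
    values, layout = [], []
    for t in passages:
        d = observed[t]
        syn, nonsyn = _sr_pair(d)
        spectrum = np.zeros(len(cells))
        k = d.classes
        tuples = np.stack([k[:, 0] + k[:, 2], k[:, 4], k[:, 1] + k[:, 3], k[:, 5]], axis=1)
        for row, f in zip(tuples.tolist(), d.freq):
            cell = tuple(row)
            if cell in index:
                spectrum[index[cell]] += f
        values += [syn, nonsyn] + list(spectrum)
        layout += [(t, "mean_syn"), (t, "mean_nonsyn")]
        layout += [(t, f"f{c}") for c in cells]
    return SummaryVector("L-LR", values, layout)


def summarize(observed: dict, kind: str, passages=None, cap: int = DEFAULT_CELL_CAP) -> SummaryVector:
    if kind == "SR":
        return sr_statistic(observed, passages)
    if kind == "LR":
        return lr_statistic(observed, passages, cap)
    if kind == "L-LR":
        return llr_statistic(observed, passages, cap)
    raise ValueError(f"unknown summary kind {kind!r}; expected one of {SUMMARY_KINDS}")


# ---------------------------------------------------------------------------
# beneficial-SNV labeling from empirical trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeneficialLabelRule:
    """Trajectory-based rule for calling beneficial SNVs.

    An SNV is beneficial if it was rare (below ``rare_threshold``) at the
    early passage but rose above ``rise_threshold`` by the late passage — in
    every replica line when ``require_all_lines``.  The default rare threshold
    of 1% is the frequency a neutral SNV is expected to reach by passage 10
    at a per-base mutation rate of 1e-3.
    """

    early_passage: int = 3
    late_passage: int = 10
    rare_threshold: float = 0.01
    rise_threshold: float = 0.03
    require_all_lines: bool = True

    def __post_init__(self):
        if self.rare_threshold >= self.rise_threshold:
            raise ValueError("rare_threshold must be below rise_threshold")


def label_beneficial(trajectories: pd.DataFrame, rule: BeneficialLabelRule | None = None) -> set:
    """Label beneficial SNVs from per-line, per-passage frequency trajectories.

    ``trajectories`` needs columns ``line``, ``passage``, ``snv`` and
    ``frequency``; absent (snv, line, passage) rows count as frequency 0.
    Returns the set of SNV identifiers satisfying the rule.
    """
    rule = rule or BeneficialLabelRule()
    if trajectories.empty:
        return set()
    lines = sorted(trajectories["line"].unique())
    freq = trajectories.pivot_table(
        index="snv", columns=["line", "passage"], values="frequency",
        aggfunc="sum", fill_value=0.0,
    )
    out = set()
    for snv, row in freq.iterrows():
        def f(line, t):
            return row.get((line, t), 0.0)
        rare = [f(ln, rule.early_passage) < rule.rare_threshold for ln in lines]
        risen = [f(ln, rule.late_passage) > rule.rise_threshold for ln in lines]
        ok = [r and h for r, h in zip(rare, risen)]
        if (all(ok) if rule.require_all_lines else any(ok)):
            out.add(snv)
    return out
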