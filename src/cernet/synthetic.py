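"""Synthetic data with planted ceRNA structure, plus its ground truth.

The generator emulates a two-group (case/control) expression study over
three transcript classes (lncRNA, miRNA, mRNA) in which a chosen number
of ceRNA triplets is planted:

* expression is simulated on the log2 scale with Gaussian noise; planted
  differentially expressed transcripts get a between-group mean shift of
  ``log2(fc_planted)``;
* each planted triplet shares one latent factor per sample that loads on
  the lncRNA and mRNA with ``+coupling`` and on the miRNA with
  ``-coupling``, so in expectation r(lnc, mRNA) > 0 and the miRNA is
  negatively correlated with both partners;
* each planted triplet's lncRNA carries one exact sequence target site
  for its miRNA: the reverse complement of miRNA positions
  ``1..site_length``, which guarantees a perfect seed match (positions
  2-8) and a strongly negative duplex energy;
* the miRNA->mRNA interaction table contains every planted pair plus
  random decoy rows, and the gene-set collection over-populates a few
  "enriched" terms with triplet mRNAs.

All randomness derives from a single integer seed through per-stage
``numpy`` SeedSequence streams, so every artifact is byte-identical
across re-runs with the same configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .diffexpr import ExpressionMatrix
from .enrichment import GeneSet, GeneSetCollection
from .targets import reverse_complement

_STREAM_EXPR, _STREAM_SEQ, _STREAM_TABLE, _STREAM_GMT = 0, 1, 2, 3

NUCLEOTIDES = np.array(list("ACGU"))


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=[int(seed), stream]))


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults define the standard study regime.

    With the defaults, the expected within-triplet lncRNA-mRNA Pearson
    correlation is (d^2/4 + coupling^2) / (d^2/4 + coupling^2 + noise_sd^2)
    with d = log2(fc_planted): about 0.995, comfortably above the 0.99
    coexpression gate; the factor-only part follows the analytic formula
    coupling^2 / (coupling^2 + noise_sd^2).
    """

    n_case: int = 20
    n_control: int = 20
    n_lnc: int = 80
    n_mi: int = 24
    n_m: int = 160
    n_triplets: int = 20
    fc_planted: float = 4.0
    coupling: float = 0.95
    noise_sd: float = 0.1
    seed: int = 0
    n_terms: int = 50
    n_enriched: int = 5
    boost: float = 10.0
    site_length: int = 14
    lnc_length: int = 300
    decoy_de_fraction: float = 0.1
    n_decoy_interactions: int = 60
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_case", "n_control", "n_lnc", "n_mi", "n_m",
                     "n_triplets", "n_terms"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.fc_planted < 1.0:
            raise ValueError("fc_planted must be >= 1 (1 = null, >2 = screenable)")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")
        if self.noise_sd <= 0.0:
            raise ValueError("noise_sd must be positive")
        if self.n_lnc < self.n_triplets or self.n_m < self.n_triplets:
            raise ValueError(
                f"cannot host {self.n_triplets} triplets with n_lnc={self.n_lnc}"
                f" and n_m={self.n_m}; need at least n_triplets of each")
        if self.n_terms < self.n_enriched:
            raise ValueError("n_terms must be >= n_enriched")
        if not 8 <= self.site_length <= 19:
            raise ValueError("site_length must lie in [8, 19] "
                             "(cover the seed, fit the shortest miRNA)")
        if self.lnc_length < 200:
            raise ValueError("lncRNAs are >= 200 nt by definition")
        if self.lnc_length < self.site_length + 7:
            raise ValueError("lnc_length too short to host a planted site")

    # deterministic id rosters -------------------------------------------

    def lnc_ids(self) -> list[str]:
        return [f"LNC{i:04d}" for i in range(1, self.n_lnc + 1)]

    def mi_ids(self) -> list[str]:
        return [f"MIR{i:03d}" for i in range(1, self.n_mi + 1)]

    def m_ids(self) -> list[str]:
        return [f"MRNA{i:04d}" for i in range(1, self.n_m + 1)]

    def term_ids(self) -> list[str]:
        return [f"TERM{i:04d}" for i in range(1, self.n_terms + 1)]


@dataclass
class GroundTruth:
    """Ledger of everything planted, for recovery scoring."""

    planted_triplets: list = field(default_factory=list)   # (lnc, mi, m)
    planted_de: dict = field(default_factory=dict)          # id -> "up"|"down"
    planted_sites: list = field(default_factory=list)       # (mi, lnc, 1-based seed start)
    enriched_terms: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(planted_triplets=[tuple(t) for t in raw["planted_triplets"]],
                   planted_de=raw["planted_de"],
                   planted_sites=[tuple(s) for s in raw["planted_sites"]],
                   enriched_terms=list(raw["enriched_terms"]))


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate the expression matrix and record the ground truth.

    Planted triplet members are all differentially expressed (lncRNA and
    mRNA in the triplet's orientation, the miRNA opposite), so the
    triplets survive the downstream screen; a ``decoy_de_fraction`` of
    each class is additionally shifted in random directions, and all
    remaining transcripts are exchangeable noise.
    """
    rng = _rng(config.seed, _STREAM_EXPR)
    lnc_ids, mi_ids, m_ids = config.lnc_ids(), config.mi_ids(), config.m_ids()
    samples = ([f"case{i:02d}" for i in range(1, config.n_case + 1)]
               + [f"ctrl{i:02d}" for i in range(1, config.n_control + 1)])
    groups = pd.Series(["case"] * config.n_case + ["control"] * config.n_control,
                       index=samples)
    n_samples = len(samples)
    case_mask = np.array([g == "case" for g in groups])

    # -- choose planted structure ----------------------------------------
    truth = GroundTruth(enriched_terms=config.term_ids()[:config.n_enriched])
    mi_pool = mi_ids[:min(config.n_triplets, config.n_mi)]
    # orientation is a property of the miRNA so that miRNAs shared across
    # triplets never face contradictory directions
    mi_orientation = {mid: int(rng.choice([1, -1])) for mid in mi_pool}
    triplets = []
    for t in range(config.n_triplets):
        lnc, mi, m = lnc_ids[t], mi_pool[t % len(mi_pool)], m_ids[t]
        triplets.append((lnc, mi, m))
    truth.planted_triplets = triplets

    d = float(np.log2(config.fc_planted))
    for lnc, mi, m in triplets:
        orient = mi_orientation[mi]
        truth.planted_de[lnc] = "up" if orient > 0 else "down"
        truth.planted_de[m] = "up" if orient > 0 else "down"
        truth.planted_de[mi] = "down" if orient > 0 else "up"
    # decoy DE transcripts, random directions, drawn after the triplet block
    for ids, used in ((lnc_ids, config.n_triplets), (mi_ids, len(mi_pool)),
                      (m_ids, config.n_triplets)):
        n_decoy = min(len(ids) - used,
                      max(1, round(config.decoy_de_fraction * len(ids))))
        for tid in ids[used:used + n_decoy]:
            truth.planted_de[tid] = "up" if rng.random() < 0.5 else "down"

    # planted site positions (sequence realisation happens later)
    for lnc, mi, m in triplets:
        q = int(rng.integers(1, config.lnc_length - config.site_length + 2))
        start = q + config.site_length - 8  # 1-based seed-window start
        truth.planted_sites.append((mi, lnc, start))

    # -- realise the matrix ----------------------------------------------
    all_ids = lnc_ids + mi_ids + m_ids
    types = pd.Series(["lnc"] * config.n_lnc + ["mi"] * config.n_mi
                      + ["m"] * config.n_m, index=all_ids)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, len(all_ids))
    values = baseline[:, None] + rng.normal(0.0, config.noise_sd,
                                            (len(all_ids), n_samples))
    row = {tid: i for i, tid in enumerate(all_ids)}
    for tid, direction in truth.planted_de.items():
        shift = d if direction == "up" else -d
        values[row[tid], case_mask] += shift
    for lnc, mi, m in triplets:
        f = rng.standard_normal(n_samples)
        values[row[lnc]] += config.coupling * f
        values[row[m]] += config.coupling * f
        values[row[mi]] -= config.coupling * f

    matrix = ExpressionMatrix(values=pd.DataFrame(values, index=all_ids,
                                                  columns=samples),
                              transcript_types=types, sample_groups=groups,
                              log2=True)
    return matrix, truth


def simulate_sequences(config: SimulationConfig,
                       truth: GroundTruth) -> tuple[dict[str, str], dict[str, str]]:
    """Emit miRNA (19-24 nt) and lncRNA (>= 200 nt) RNA sequences.

    Each planted site embeds the reverse complement of its miRNA's
    positions ``1..site_length`` so that the seed window (positions 2-8)
    matches exactly at the recorded start; background sequence is uniform
    random with no guaranteed sites.
    """
    rng = _rng(config.seed, _STREAM_SEQ)
    mirnas = {mid: "".join(rng.choice(NUCLEOTIDES, int(rng.integers(19, 25))))
              for mid in config.mi_ids()}
    lncs = {lid: "".join(rng.choice(NUCLEOTIDES, config.lnc_length))
            for lid in config.lnc_ids()}
    for mi, lnc, start in truth.planted_sites:
        if mi not in mirnas or lnc not in lncs:
            raise ValueError(f"planted site references unknown ids ({mi}, {lnc})")
        if start + 6 > len(lncs[lnc]):
            raise ValueError(f"planted site at {start} overruns transcript {lnc}")
        q0 = start - (config.site_length - 8) - 1  # 0-based motif start
        if q0 < 0 or q0 + config.site_length > len(lncs[lnc]):
            raise ValueError(f"planted context at {start} overruns transcript {lnc}")
        motif = reverse_complement(mirnas[mi][:config.site_length])
        s = lncs[lnc]
        lncs[lnc] = s[:q0] + motif + s[q0 + config.site_length:]
    return mirnas, lncs


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid, seq in seqs.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def simulate_interaction_table(config: SimulationConfig,
                               truth: GroundTruth) -> pd.DataFrame:
    """miRNA->mRNA table: every planted pair plus random decoy rows.

    Emulates the union of two curated-database exports; about half of the
    planted pairs appear in both sources so the loader's de-duplication
    path is exercised.
    """
    rng = _rng(config.seed, _STREAM_TABLE)
    sources = ("miRTarBase-sim", "miRWalk-sim")
    planted = {(mi, m) for _, mi, m in truth.planted_triplets}
    rows = []
    for lnc, mi, m in truth.planted_triplets:
        rows.append((mi, m, sources[0]))
        if rng.random() < 0.5:
            rows.append((mi, m, sources[1]))
    candidates = [(mi, m) for mi in config.mi_ids() for m in config.m_ids()
                  if (mi, m) not in planted]
    n_decoys = min(config.n_decoy_interactions, len(candidates))
    for idx in rng.choice(len(candidates), size=n_decoys, replace=False):
        mi, m = candidates[int(idx)]
        rows.append((mi, m, sources[int(rng.integers(0, 2))]))
    return pd.DataFrame(rows, columns=["miRNA", "mRNA", "source"])


def write_interaction_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def simulate_genesets(config: SimulationConfig,
                      truth: GroundTruth) -> GeneSetCollection:
    """Gene sets over the mRNA universe, with planted enriched terms.

    Members of ``truth.enriched_terms`` are drawn with sampling weight
    ``boost`` (default 10x) on planted-triplet mRNAs; all other terms
    draw uniformly.  ``boost=1`` removes the planted structure entirely.
    """
    rng = _rng(config.seed, _STREAM_GMT)
    universe = config.m_ids()
    triplet_mrnas = {m for _, _, m in truth.planted_triplets}
    categories = ("BP", "MF", "CC", "pathway")
    lo = min(10, max(2, config.n_m // 4))
    hi = max(lo, min(40, config.n_m // 2))
    weights = np.array([config.boost if g in triplet_mrnas else 1.0
                        for g in universe])
    weights /= weights.sum()
    uniform = np.full(len(universe), 1.0 / len(universe))
    terms = []
    enriched = set(truth.enriched_terms)
    for i, term_id in enumerate(config.term_ids()):
        size = int(rng.integers(lo, hi + 1))
        p = weights if term_id in enriched else uniform
        members = rng.choice(len(universe), size=size, replace=False, p=p)
        terms.append(GeneSet(term_id=term_id, name=categories[i % 4],
                             category=categories[i % 4],
                             members=frozenset(universe[j] for j in members)))
    return GeneSetCollection(terms=terms, universe=frozenset(universe))


# -- recovery scoring -------------------------------------------------------

def score_de_recovery(truth: GroundTruth, screened: pd.DataFrame) -> dict:
    """Recall of planted DE transcripts and false-positive rate elsewhere."""
    planted = set(truth.planted_de)
    passing = set(screened.index[screened["passes"]])
    nulls = set(screened.index) - planted
    return {
        "recall": len(passing & planted) / len(planted) if planted else float("nan"),
        "fpr": len(passing & nulls) / len(nulls) if nulls else float("nan"),
        "n_planted": len(planted),
        "n_passing": len(passing),
    }


def score_triplet_recovery(truth: GroundTruth, triplets) -> dict:
    """Exact-membership recall and precision of recovered triplets."""
    true = {tuple(t) for t in truth.planted_triplets}
    found = {(t.lnc_id, t.mi_id, t.m_id) for t in triplets}
    return {
        "recall": len(found & true) / len(true) if true else float("nan"),
        "precision": len(found & true) / len(found) if found else float("nan"),
        "n_true": len(true),
        "n_found": len(found),
    }
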