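"""miRNA target determination.

miRNA -> lncRNA interactions are predicted from sequence: a candidate site
is a transcript window that is the exact reverse complement (Watson-Crick
only, no G:U wobble) of the miRNA seed, positions 2-8 counted 1-based from
the 5' end.  Each candidate is then scored with a simplified
intermolecular duplex energy model, and the pair is kept when its best
(most negative) site energy clears an MFE threshold.

miRNA -> mRNA interactions are not predicted; they are loaded from
tab-separated interaction tables in the style of curated target databases
(miRTarBase / miRWalk exports) and de-duplicated across sources.

The duplex model is a deliberately small surrogate for full hybridization
tools: stacked base pairs contribute the mean of their two per-pair
energies (G:C -3.0, A:U -2.0, G:U -1.0 kcal/mol), interior loops and
bulges pay an affine penalty (+4.0 open, +0.5 per unpaired nucleotide),
dangling ends are free and intramolecular structure is ignored.  It is
not RNAhybrid or miRanda; its contract is monotonicity (more
complementarity never scores worse) and exact agreement with exhaustive
alignment enumeration, both enforced by the test suite.

Coordinates in all outputs are 1-based, inclusive, on the transcript's
sense strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: seed = miRNA positions 2..8 inclusive, 1-based (canonical 7-mer seed)
SEED_START, SEED_END = 2, 8
SEED_LEN = SEED_END - SEED_START + 1


@dataclass(frozen=True)
class EnergyModel:
    """Parameters of the surrogate duplex energy function (kcal/mol)."""

    gc: float = -3.0
    au: float = -2.0
    gu: float = -1.0
    loop_open: float = 4.0
    loop_extend: float = 0.5

    def pair_energy(self, x: str, y: str) -> float | None:
        """Energy label of base pair x:y, or None if unpairable."""
        pair = x + y
        if pair in ("GC", "CG"):
            return self.gc
        if pair in ("AU", "UA"):
            return self.au
        if pair in ("GU", "UG"):
            return self.gu
        return None


DEFAULT_ENERGY_MODEL = EnergyModel()


@dataclass
class SeedSite:
    """One seed-complementary site on a transcript."""

    mirna_id: str
    transcript_id: str
    start: int                      # 1-based, 5'-most matched transcript position
    seed_span: tuple[int, int] = (SEED_START, SEED_END)
    mfe: float | None = None        # kcal/mol once scored


@dataclass
class TargetPair:
    """A miRNA -> target interaction with its evidence."""

    mirna_id: str
    target_id: str
    target_class: str               # "lnc" | "m"
    evidence: str                   # "predicted" | "table"
    best_mfe: float | None = None
    n_sites: int = 0
    sources: tuple[str, ...] = field(default_factory=tuple)


def clean_rna(seq: str, *, what: str = "sequence") -> str:
    """Uppercase, convert T->U, and validate the RNA alphabet."""
    s = str(seq).upper().replace("T", "U")
    for ch in s:
        if ch not in "ACGU":
            raise ValueError(f"invalid nucleotide {ch!r} in {what}")
    return s


def reverse_complement(seq: str) -> str:
    return "".join(RNA_COMPLEMENT[c] for c in reversed(seq))


def seed_scan(mirna_seq: str, transcript_seq: str,
              mirna_id: str = "mirna", transcript_id: str = "transcript") -> list[SeedSite]:
    """Find every perfect seed-complementary site on a transcript.

    A site is reported at each transcript position (1-based start) whose
    7-nt window equals the reverse complement of miRNA positions 2-8.
    Overlapping sites are all reported, ordered by start.
    """
    mi = clean_rna(mirna_seq, what=f"miRNA {mirna_id}")
    tx = clean_rna(transcript_seq, what=f"transcript {transcript_id}")
    if len(mi) < SEED_END:
        raise ValueError(f"miRNA {mirna_id} shorter than {SEED_END} nt")
    if not tx:
        raise ValueError(f"transcript {transcript_id} is empty")
    motif = reverse_complement(mi[SEED_START - 1:SEED_END])
    sites, pos = [], tx.find(motif)
    while pos != -1:
        sites.append(SeedSite(mirna_id=mirna_id, transcript_id=transcript_id,
                              start=pos + 1))
        pos = tx.find(motif, pos + 1)
    return sites


def duplex_mfe(mirna_seq: str, site_context: str,
               model: EnergyModel = DEFAULT_ENERGY_MODEL) -> float:
    """Minimum free energy of the intermolecular duplex (kcal/mol).

    Minimum over all antiparallel alignments of the two strands of the
    summed stack energies plus affine loop penalties.  The empty duplex
    scores 0.0, so the result is never positive.
    """
    a = clean_rna(mirna_seq, what="miRNA")
    b = clean_rna(site_context, what="site context")
    if not a or not b:
        raise ValueError("empty sequence")
    # Reverse the target so pairs advance in the same direction on both
    # strands; pair (i, j) then means a[i] with original b[len(b)-1-j].
    br = b[::-1]
    n, m = len(a), len(br)
    pe = [[model.pair_energy(a[i], br[j]) for j in range(m)] for i in range(n)]
    INF = float("inf")
    # P[i][j]: best energy of an alignment whose last pair is (i, j).
    # G[i][j]: best energy of "last pair strictly before (i, j)" plus the
    #          affine penalty for the unpaired stretch consumed so far.
    P = [[INF] * m for _ in range(n)]
    G = [[INF] * m for _ in range(n)]
    best = 0.0
    open_cost = model.loop_open + model.loop_extend
    for i in range(n):
        for j in range(m):
            g = INF
            if i > 0:
                g = min(g, G[i - 1][j] + model.loop_extend,
                        P[i - 1][j] + open_cost)
            if j > 0:
                g = min(g, G[i][j - 1] + model.loop_extend,
                        P[i][j - 1] + open_cost)
            G[i][j] = g
            if pe[i][j] is not None:
                p = 0.0  # open a fresh duplex; dangling ends are free
                if i > 0 and j > 0:
                    if pe[i - 1][j - 1] is not None and P[i - 1][j - 1] < INF:
                        stack = (pe[i - 1][j - 1] + pe[i][j]) / 2.0
                        p = min(p, P[i - 1][j - 1] + stack)
                    p = min(p, G[i - 1][j - 1])
                P[i][j] = p
                best = min(best, p)
    return best


def site_context(transcript_seq: str, site: SeedSite, flank: int = 10) -> str:
    """Transcript window around a seed site, +/- ``flank`` nt."""
    lo = max(0, site.start - 1 - flank)
    hi = min(len(transcript_seq), site.start - 1 + SEED_LEN + flank)
    return transcript_seq[lo:hi]


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> RNA sequence mapping."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seqs[rec.id] = clean_rna(str(rec.seq), what=rec.id)
    return seqs


def predict_lnc_targets(mirna_fasta, lnc_fasta, mfe_cut: float | None = -20.0,
                        flank: int = 10,
                        model: EnergyModel = DEFAULT_ENERGY_MODEL) -> list[TargetPair]:
    """Predict miRNA -> lncRNA pairs by seed scan + duplex-energy filter.

    A pair is reported iff at least one seed site exists whose duplex
    energy (computed on the site context +/- ``flank`` nt) is <= ``mfe_cut``;
    ``mfe_cut=None`` disables the energy gate.  ``best_mfe`` is the minimum
    over the pair's retained sites.
    """
    mirnas = mirna_fasta if isinstance(mirna_fasta, dict) else read_fasta(mirna_fasta)
    lncs = lnc_fasta if isinstance(lnc_fasta, dict) else read_fasta(lnc_fasta)
    collisions = set(mirnas) & set(lncs)
    if collisions:
        raise ValueError(f"ids present in both FASTAs: {sorted(collisions)}")
    pairs: list[TargetPair] = []
    for mid, mseq in mirnas.items():
        for lid, lseq in lncs.items():
            sites = seed_scan(mseq, lseq, mirna_id=mid, transcript_id=lid)
            kept = []
            for s in sites:
                s.mfe = duplex_mfe(mseq, site_context(lseq, s, flank=flank), model)
                if mfe_cut is None or s.mfe <= mfe_cut:
                    kept.append(s)
            if kept:
                pairs.append(TargetPair(
                    mirna_id=mid, target_id=lid, target_class="lnc",
                    evidence="predicted",
                    best_mfe=min(s.mfe for s in kept), n_sites=len(kept)))
    return pairs


def load_mirna_mrna_table(tsv_path) -> list[TargetPair]:
    """Load and de-duplicate a miRNA -> mRNA interaction table.

    Expects a header line ``miRNA<TAB>mRNA<TAB>source``; duplicate pairs
    are merged with their provenance labels unioned.  Malformed rows raise
    with 1-based line numbers.
    """
    path = Path(tsv_path)
    merged: dict[tuple[str, str], set[str]] = {}
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [c.strip().lower() for c in header[:3]] != ["mirna", "mrna", "source"]:
            raise ValueError(f"{path}: expected header miRNA<TAB>mRNA<TAB>source")
        bad: list[int] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not all(f.strip() for f in fields[:3]):
                bad.append(lineno)
                continue
            mi, m, src = (f.strip() for f in fields[:3])
            merged.setdefault((mi, m), set()).add(src)
        if bad:
            raise ValueError(f"{path}: malformed rows at lines {bad}")
    return [TargetPair(mirna_id=mi, target_id=m, target_class="m",
                       evidence="table", sources=tuple(sorted(srcs)))
            for (mi, m), srcs in sorted(merged.items())]


def write_target_pairs(pairs: list[TargetPair], path) -> None:
    """Write target pairs as TSV (coordinates documented in the header)."""
    with open(path, "w") as fh:
        fh.write("# site coordinates: 1-based, inclusive, transcript sense strand\n")
        fh.write("mirna_id\ttarget_id\ttarget_class\tevidence\tbest_mfe\tn_sites\tsources\n")
        for p in pairs:
            mfe = "" if p.best_mfe is None else f"{p.best_mfe:.4g}"
            fh.write(f"{p.mirna_id}\t{p.target_id}\t{p.target_class}\t"
                     f"{p.evidence}\t{mfe}\t{p.n_sites}\t{','.join(p.sources)}\n")
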