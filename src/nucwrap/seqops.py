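"""Sequences over the extended alphabet {A, C, G, T, MpN, HpK}.

A :class:`ModSequence` is a plain A/C/G/T string plus a set of symmetric
CpG-step modifications: an annotation ``(j, kind)`` marks the CpG step at
1-based junction ``j`` (``bases[j-1:j+1] == "CG"``) as carrying either
5-methyl (``"methyl"``, step label MN) or 5-hydroxymethyl
(``"hydroxymethyl"``, step label HK) groups on both strands' cytosines.
Modifications are annotations on junctions, never extra letters; the
extended-FASTA dialect writes a modified step as the letter pair ``MN``
or ``HK`` in place of ``CG``.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ModSequence",
    "MOD_KINDS",
    "count_cpg",
    "apply_symmetric_modification",
    "reverse_complement",
    "random_sequence_with_cpg_range",
    "dinucleotide_counts",
    "altschul_erickson_shuffle",
    "tetramer_context_counts",
    "step_labels",
    "read_fasta",
    "write_fasta",
]

MOD_KINDS = ("methyl", "hydroxymethyl")
_MOD_LETTERS = {"methyl": "MN", "hydroxymethyl": "HK"}
_ALPHABET = frozenset("ACGT")
_COMP = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class ModSequence:
    """An A/C/G/T string with symmetric CpG-step modifications."""

    bases: str
    mods: frozenset = field(default_factory=frozenset)
    name: str | None = None

    def __post_init__(self):
        bases = self.bases.upper()
        object.__setattr__(self, "bases", bases)
        bad = set(bases) - _ALPHABET
        if bad:
            raise ValueError(
                f"sequence contains letters outside A/C/G/T: {sorted(bad)}")
        mods = frozenset((int(j), str(k)) for j, k in self.mods)
        object.__setattr__(self, "mods", mods)
        seen = set()
        n = len(bases)
        for j, kind in sorted(mods):
            if kind not in MOD_KINDS:
                raise ValueError(f"unknown modification kind {kind!r}")
            if not 1 <= j <= n - 1:
                raise ValueError(f"modification step index {j} out of range")
            if bases[j - 1 : j + 1] != "CG":
                raise ValueError(f"step {j} is not a CpG step")
            if j in seen:
                raise ValueError(f"step {j} annotated more than once")
            seen.add(j)

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def mod_map(self) -> dict:
        return dict(self.mods)


def count_cpg(seq: ModSequence | str) -> int:
    """Number of CpG junctions (modified or not)."""
    bases = seq.bases if isinstance(seq, ModSequence) else str(seq).upper()
    return sum(1 for j in range(len(bases) - 1) if bases[j : j + 2] == "CG")


def _cpg_junctions(bases: str):
    return [j + 1 for j in range(len(bases) - 1) if bases[j : j + 2] == "CG"]


def apply_symmetric_modification(seq: ModSequence, kind: str) -> ModSequence:
    """Annotate every CpG step with the given modification kind.

    Refuses if another kind is already present anywhere (the parameter
    alphabet has no mixed-modification steps)."""
    if kind not in MOD_KINDS:
        raise ValueError(f"unknown modification kind {kind!r}")
    other = {k for _, k in seq.mods if k != kind}
    if other:
        raise ValueError(
            f"sequence already carries {sorted(other)} modifications; "
            "mixed-kind annotation is not supported")
    mods = frozenset((j, kind) for j in _cpg_junctions(seq.bases))
    return ModSequence(seq.bases, mods, name=seq.name)


def reverse_complement(seq: ModSequence) -> ModSequence:
    """Watson/Crick swap; a modified step at junction j maps to n - j."""
    n = len(seq.bases)
    bases = seq.bases.translate(_COMP)[::-1]
    mods = frozenset((n - j, kind) for j, kind in seq.mods)
    return ModSequence(bases, mods, name=seq.name)


def random_sequence_with_cpg_range(
    n_bp: int, cpg_min: int, cpg_max: int, rng_seed
) -> ModSequence:
    """Uniform i.i.d. sequence adjusted to a target CpG-count range.

    The sequence is drawn with equal base probabilities; then random
    dinucleotide positions are overwritten with CG (to raise the count)
    or a random CpG has its C replaced by a uniform draw from {A, T, G}
    (to lower it), re-counting after every edit, until the CpG count
    falls in [cpg_min, cpg_max].
    """
    if not 0 <= cpg_min <= cpg_max:
        raise ValueError("need 0 <= cpg_min <= cpg_max")
    if cpg_min > n_bp // 2:
        raise ValueError(
            f"cpg_min={cpg_min} infeasible for {n_bp} bp (max {n_bp // 2})")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    bases = list(rng.choice(list("ACGT"), size=n_bp))
    for _ in range(100 * n_bp):
        cpg = _cpg_junctions("".join(bases))
        c = len(cpg)
        if cpg_min <= c <= cpg_max:
            return ModSequence("".join(bases))
        if c < cpg_min:
            non_cg = [j for j in range(n_bp - 1)
                      if bases[j] != "C" or bases[j + 1] != "G"]
            j = int(non_cg[rng.integers(len(non_cg))])
            bases[j], bases[j + 1] = "C", "G"
        else:
            j = int(cpg[rng.integers(c)]) - 1
            bases[j] = "ATG"[rng.integers(3)]
    raise RuntimeError("CpG adjustment did not terminate")  # pragma: no cover


def dinucleotide_counts(seq: ModSequence | str) -> dict:
    """Counts of the 16 dinucleotide steps over all n-1 junctions."""
    bases = seq.bases if isinstance(seq, ModSequence) else str(seq).upper()
    if len(bases) < 2:
        raise ValueError("need at least 2 bases")
    counts = {a + b: 0 for a in "ACGT" for b in "ACGT"}
    for j in range(len(bases) - 1):
        counts[bases[j : j + 2]] += 1
    return counts


def altschul_erickson_shuffle(seq: ModSequence | str, rng_seed) -> ModSequence:
    """Uniform dinucleotide-preserving shuffle (Eulerian-path sampling).

    The sequence's junctions form a multigraph on the bases; a shuffle is
    an Eulerian walk from the first to the last base.  For every vertex
    other than the terminal one a random last-exit edge is drawn and the
    draw is accepted only if the last-exit edges form an arborescence
    into the terminal vertex; the remaining edges are then permuted
    uniformly.  The output has exactly the input's dinucleotide counts
    (hence the same first and last base).
    """
    if isinstance(seq, ModSequence):
        if seq.mods:
            raise ValueError("shuffle an unmodified sequence; re-annotate afterwards")
        bases = seq.bases
    else:
        bases = str(seq).upper()
    if len(bases) < 2:
        raise ValueError("need at least 2 bases")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    first, last = bases[0], bases[-1]
    edges = defaultdict(list)
    for j in range(len(bases) - 1):
        edges[bases[j]].append(bases[j + 1])

    sources = [v for v in edges if v != last]
    for _ in range(100000):
        last_exit = {v: edges[v][rng.integers(len(edges[v]))] for v in sources}
        ok = True
        for v in sources:
            seen = {v}
            u = v
            while u != last:
                if u not in last_exit:  # dead end off the arborescence
                    ok = False
                    break
                u = last_exit[u]
                if u in seen:
                    ok = False
                    break
                seen.add(u)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover
        raise RuntimeError("arborescence sampling did not terminate")

    order = {}
    for v, targets in edges.items():
        rest = list(targets)
        if v in last_exit:
            rest.remove(last_exit[v])
        rest = [rest[i] for i in rng.permutation(len(rest))]
        if v in last_exit:
            rest.append(last_exit[v])
        order[v] = rest

    out = [first]
    ptr = defaultdict(int)
    u = first
    for _ in range(len(bases) - 1):
        nxt = order[u][ptr[u]]
        ptr[u] += 1
        out.append(nxt)
        u = nxt
    return ModSequence("".join(out))


def tetramer_context_counts(seqs) -> dict:
    """Position-frequency counts of the 4 bases flanking CpG steps.

    Returns ``{"upstream": (4,4) array, "downstream": (4,4) array,
    "n_steps": tallied CpG steps, "n_skipped": steps too close to an
    end}``; rows index A/C/G/T, columns the positions -4..-1 (upstream)
    and +1..+4 (downstream) of the step.  Column sums equal ``n_steps``.
    """
    base_idx = {b: i for i, b in enumerate("ACGT")}
    up = np.zeros((4, 4), dtype=int)
    down = np.zeros((4, 4), dtype=int)
    n_steps = n_skipped = 0
    for seq in seqs:
        bases = seq.bases if isinstance(seq, ModSequence) else str(seq).upper()
        n = len(bases)
        for j in _cpg_junctions(bases):
            if j < 5 or j > n - 5:
                n_skipped += 1
                continue
            n_steps += 1
            for p in range(4):
                up[base_idx[bases[j - 5 + p]], p] += 1
                down[base_idx[bases[j + 1 + p]], p] += 1
    return {"upstream": up, "downstream": down,
            "n_steps": n_steps, "n_skipped": n_skipped}


def step_labels(seq: ModSequence) -> list[str]:
    """Per-junction dimer-step labels, with MN/HK for modified CpG steps."""
    mods = seq.mod_map
    labels = []
    for j in range(len(seq.bases) - 1):
        kind = mods.get(j + 1)
        labels.append(_MOD_LETTERS[kind] if kind else seq.bases[j : j + 2])
    return labels


# ---------------------------------------------------------------------------
# Extended FASTA


def _encode_extended(seq: ModSequence) -> str:
    chars = list(seq.bases)
    for j, kind in seq.mods:
        chars[j - 1], chars[j] = _MOD_LETTERS[kind]
    return "".join(chars)


def _decode_extended(text: str) -> tuple[str, frozenset]:
    chars = list(text.upper())
    mods = []
    j = 0
    while j < len(chars):
        ch = chars[j]
        if ch in "MH":
            pair = "MN" if ch == "M" else "HK"
            kind = "methyl" if ch == "M" else "hydroxymethyl"
            if j + 1 >= len(chars) or chars[j + 1] != pair[1]:
                raise ValueError(
                    f"letter {ch} at position {j + 1} not followed by {pair[1]}")
            chars[j], chars[j + 1] = "C", "G"
            mods.append((j + 1, kind))
            j += 2
        elif ch in "NK":
            raise ValueError(f"orphan modified letter {ch} at position {j + 1}")
        else:
            j += 1
    return "".join(chars), frozenset(mods)


def read_fasta(path) -> list[ModSequence]:
    """Read (extended) FASTA: MN / HK letter pairs become modified steps."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        bases, mods = _decode_extended(str(rec.seq))
        out.append(ModSequence(bases, mods, name=rec.id))
    return out


def write_fasta(seqs, path) -> None:
    records = []
    for i, seq in enumerate(seqs):
        records.append(SeqRecord(Seq(_encode_extended(seq)),
                                 id=seq.name or f"seq{i + 1}", description=""))
    SeqIO.write(records, str(path), "fasta")
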