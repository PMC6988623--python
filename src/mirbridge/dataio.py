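"""Edge-list / sequence I/O and curation of the heterogeneous dataset.

The raw inputs are two bipartite interaction edge lists — lncRNA–miRNA and
protein–miRNA — plus optional FASTA sequence files.  Curation restricts
both networks to the miRNAs they share, so that every retained miRNA can
mediate between at least one lncRNA and one protein.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: sentinel replacing ambiguous residues; it never scores as a match in
#: alignment and is dropped before feature computation
AMBIGUOUS_SENTINEL = "*"

_HEADER_ENTITY = {"entity_id", "lncrna_id", "lnc_id", "protein_id", "prot_id"}
_HEADER_MIRNA = {"mirna_id", "mirna", "microrna_id"}


class EntityClass(str, Enum):
    LNCRNA = "lncRNA"
    PROTEIN = "protein"


class Alphabet(str, Enum):
    NUCLEOTIDE = "nucleotide"
    AMINO_ACID = "amino_acid"


@dataclass
class EdgeList:
    """Unique (entity, miRNA) interaction pairs for one entity class."""

    pairs: list[tuple[str, str]]
    entity_class: EntityClass

    @property
    def entities(self) -> set[str]:
        return {e for e, _ in self.pairs}

    @property
    def mirnas(self) -> set[str]:
        return {m for _, m in self.pairs}


@dataclass
class SequenceStore:
    """Mapping from entity id to a cleaned sequence string.

    Nucleotide sequences use T internally (U is converted on read);
    residues outside the alphabet are replaced by a sentinel character
    that never matches in alignment.
    """

    sequences: dict[str, str]
    alphabet: Alphabet

    def __len__(self) -> int:
        return len(self.sequences)

    def __contains__(self, key: str) -> bool:
        return key in self.sequences

    def __getitem__(self, key: str) -> str:
        return self.sequences[key]


@dataclass
class InteractionNetwork:
    """Bipartite entity x miRNA network as a dense binary adjacency."""

    entity_ids: list[str]
    mirna_ids: list[str]
    adjacency: np.ndarray  # shape (n_entities, n_mirnas), values in {0, 1}
    entity_class: EntityClass

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=np.uint8)
        if self.adjacency.shape != (len(self.entity_ids), len(self.mirna_ids)):
            raise ValueError("adjacency shape does not match id lists")
        if not np.all((self.adjacency == 0) | (self.adjacency == 1)):
            raise ValueError("adjacency must be binary")

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    @property
    def mirna_degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(np.int64)

    @classmethod
    def from_pairs(
        cls,
        pairs: list[tuple[str, str]],
        entity_class: EntityClass,
        mirna_ids: list[str] | None = None,
    ) -> "InteractionNetwork":
        entity_ids = sorted({e for e, _ in pairs})
        if mirna_ids is None:
            mirna_ids = sorted({m for _, m in pairs})
        ei = {e: i for i, e in enumerate(entity_ids)}
        mi = {m: i for i, m in enumerate(mirna_ids)}
        adj = np.zeros((len(entity_ids), len(mirna_ids)), dtype=np.uint8)
        for e, m in pairs:
            adj[ei[e], mi[m]] = 1
        return cls(entity_ids, list(mirna_ids), adj, entity_class)

    def to_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i, e in enumerate(self.entity_ids):
            for j in np.flatnonzero(self.adjacency[i]):
                out.append((e, self.mirna_ids[j]))
        return out


@dataclass
class HeterogeneousDataset:
    """The pair of curated networks sharing one common miRNA ordering."""

    lnc_net: InteractionNetwork
    prot_net: InteractionNetwork
    lnc_seqs: SequenceStore | None = None
    prot_seqs: SequenceStore | None = None

    def __post_init__(self) -> None:
        if self.lnc_net.mirna_ids != self.prot_net.mirna_ids:
            raise ValueError("the two networks must share one miRNA ordering")
        if not (self.x >= 1 and self.y >= 1 and self.z >= 1):
            raise ValueError("dataset must contain >= 1 lncRNA, miRNA and protein")

    @property
    def lnc_ids(self) -> list[str]:
        return self.lnc_net.entity_ids

    @property
    def mirna_ids(self) -> list[str]:
        return self.lnc_net.mirna_ids

    @property
    def prot_ids(self) -> list[str]:
        return self.prot_net.entity_ids

    @property
    def x(self) -> int:
        return len(self.lnc_ids)

    @property
    def y(self) -> int:
        return len(self.mirna_ids)

    @property
    def z(self) -> int:
        return len(self.prot_ids)

    def profile(self) -> dict:
        """Headline curation counts (entities, miRNAs, edges)."""
        return {
            "n_lncrnas": self.x,
            "n_mirnas": self.y,
            "n_proteins": self.z,
            "n_lnc_mirna_edges": self.lnc_net.n_edges,
            "n_prot_mirna_edges": self.prot_net.n_edges,
        }


def _split_row(line: str) -> list[str]:
    if "\t" in line:
        return [f.strip() for f in line.split("\t")]
    return [f.strip() for f in line.split(",")]


def read_edge_list(path: str | Path, entity_class: EntityClass) -> EdgeList:
    """Read a two-column (entity_id, mirna_id) TSV/CSV edge list.

    A header row naming the columns is skipped if present; extra columns
    are ignored; duplicate pairs are collapsed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    entity_class = EntityClass(entity_class)
    seen: dict[tuple[str, str], None] = {}
    n_rows = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = _split_row(line)
            if len(fields) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 2 columns, got {len(fields)}"
                )
            a, b = fields[0], fields[1]
            if n_rows == 0 and (
                a.lower() in _HEADER_ENTITY or b.lower() in _HEADER_MIRNA
            ):
                n_rows += 1
                continue
            if not a or not b:
                raise ValueError(f"{path}:{lineno}: blank identifier field")
            seen[(a, b)] = None
            n_rows += 1
    if not seen:
        raise ValueError(f"{path}: no interaction pairs found")
    pairs = list(seen)
    log.info(
        "read %d unique %s-miRNA pairs from %s", len(pairs), entity_class.value, path
    )
    return EdgeList(pairs=pairs, entity_class=entity_class)


def write_edge_list(edges: EdgeList, path: str | Path) -> None:
    header = (
        "entity_id\tmirna_id"
        if edges.entity_class is EntityClass.LNCRNA
        else "entity_id\tmirna_id"
    )
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for e, m in sorted(edges.pairs):
            fh.write(f"{e}\t{m}\n")


def _clean_sequence(seq: str, alphabet: Alphabet, record_id: str) -> str:
    seq = seq.strip().upper()
    if alphabet is Alphabet.NUCLEOTIDE:
        seq = seq.replace("U", "T")
        allowed = set(NUCLEOTIDES)
    else:
        allowed = set(AMINO_ACIDS)
    n_bad = sum(1 for ch in seq if ch not in allowed)
    if n_bad:
        log.warning(
            "%s: %d residue(s) outside the %s alphabet replaced by sentinel",
            record_id,
            n_bad,
            alphabet.value,
        )
        seq = "".join(ch if ch in allowed else AMBIGUOUS_SENTINEL for ch in seq)
    return seq


def read_fasta(path: str | Path, alphabet: Alphabet) -> SequenceStore:
    """Read a FASTA file into a SequenceStore.

    Nucleotide sequences are normalized U -> T; ambiguous residues are
    replaced by a non-matching sentinel (a logged choice).
    """
    path = Path(path)
    alphabet = Alphabet(alphabet)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"{path}: duplicate FASTA header id {record.id!r}")
        seq = _clean_sequence(str(record.seq), alphabet, record.id)
        if not seq:
            raise ValueError(f"{path}: empty sequence for record {record.id!r}")
        sequences[record.id] = seq
    if not sequences:
        raise ValueError(f"{path}: no FASTA records found")
    log.info("read %d %s sequences from %s", len(sequences), alphabet.value, path)
    return SequenceStore(sequences=sequences, alphabet=alphabet)


def write_fasta(store: SequenceStore, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(store.sequences.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def curate(
    lnc_edges: EdgeList,
    prot_edges: EdgeList,
    lnc_seqs: SequenceStore | None = None,
    prot_seqs: SequenceStore | None = None,
) -> HeterogeneousDataset:
    """Restrict both edge lists to their common miRNAs.

    miRNAs appearing in only one of the two networks cannot mediate a
    lncRNA-protein pair and are dropped together with their edges;
    entities left without any edge are dropped too.  All identifier
    lists are sorted, so the curated dataset is bit-reproducible.
    """
    if lnc_edges.entity_class is not EntityClass.LNCRNA:
        raise ValueError("first edge list must have entity_class lncRNA")
    if prot_edges.entity_class is not EntityClass.PROTEIN:
        raise ValueError("second edge list must have entity_class protein")
    common = lnc_edges.mirnas & prot_edges.mirnas
    if not common:
        raise ValueError("no shared miRNAs between the two networks")
    mirna_ids = sorted(common)
    lnc_pairs = sorted((e, m) for e, m in lnc_edges.pairs if m in common)
    prot_pairs = sorted((e, m) for e, m in prot_edges.pairs if m in common)
    lnc_net = InteractionNetwork.from_pairs(
        lnc_pairs, EntityClass.LNCRNA, mirna_ids=mirna_ids
    )
    prot_net = InteractionNetwork.from_pairs(
        prot_pairs, EntityClass.PROTEIN, mirna_ids=mirna_ids
    )
    ds = HeterogeneousDataset(
        lnc_net=lnc_net, prot_net=prot_net, lnc_seqs=lnc_seqs, prot_seqs=prot_seqs
    )
    log.info("curated dataset: %s", ds.profile())
    return ds


def write_dataset(ds: HeterogeneousDataset, outdir: str | Path) -> None:
    """Dump a curated dataset as three id lists and two edge TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, ids in [
        ("lncrna_ids.txt", ds.lnc_ids),
        ("mirna_ids.txt", ds.mirna_ids),
        ("protein_ids.txt", ds.prot_ids),
    ]:
        (outdir / name).write_text("\n".join(ids) + "\n")
    for name, net in [
        ("lncrna_mirna_edges.tsv", ds.lnc_net),
        ("protein_mirna_edges.tsv", ds.prot_net),
    ]:
        with open(outdir / name, "w") as fh:
            fh.write("entity_id\tmirna_id\n")
            for e, m in net.to_pairs():
                fh.write(f"{e}\t{m}\n")


def find_supplementary(root: str | Path | None = None) -> dict[str, Path] | None:
    """Locate the curated RAID v2.0 supplementary edge lists, if present.

    Looks for ``lncrna_mirna.tsv``, ``protein_mirna.tsv`` and
    ``lncrna_protein_gold.tsv`` under ``<root>/data/supplementary``
    (default root: current working directory).  Returns the mapping of
    paths when all three exist; otherwise logs an explicit degradation
    warning and returns None, so callers can fall back to synthetic data
    instead of failing silently.
    """
    root = Path(root) if root is not None else Path.cwd()
    base = root / "data" / "supplementary"
    wanted = {
        "lnc_mirna": base / "lncrna_mirna.tsv",
        "prot_mirna": base / "protein_mirna.tsv",
        "gold": base / "lncrna_protein_gold.tsv",
    }
    if all(p.exists() for p in wanted.values()):
        return wanted
    log.warning(
        "supplementary RAID edge lists not found under %s; workflows that "
        "reproduce the curated-database results are unavailable and only "
        "synthetic datasets can be analysed",
        base,
    )
    return None
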