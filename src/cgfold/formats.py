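"""Text-format I/O and MSA depth.

Readers/writers for the community formats the pipeline touches: CASP RR
contact predictions, PSIPRED SS2 secondary-structure files, aligned
FASTA / A3M alignments and Cα-trace PDB files, plus the effective MSA
depth Nf used to gate restraint selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .geometry import CoarseStructure

AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1TO3 = {v: k for k, v in AA3TO1.items()}


class ParseError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class ContactPrediction:
    """One predicted residue–residue contact (1-based indices, i < j)."""

    i: int
    j: int
    confidence: float
    predictor_id: str = ""

    def __post_init__(self):
        if not (1 <= self.i < self.j):
            raise ValueError(f"require 1 <= i < j, got ({self.i}, {self.j})")
        if not (np.isfinite(self.confidence) and 0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def separation(self) -> int:
        return self.j - self.i


@dataclass
class ContactMap:
    """All contact predictions of one predictor for one target."""

    L: int
    predictions: list[ContactPrediction] = field(default_factory=list)
    predictor_id: str = ""

    def __post_init__(self):
        seen = set()
        for p in self.predictions:
            if p.j > self.L:
                raise ValueError(f"contact ({p.i},{p.j}) exceeds length {self.L}")
            if (p.i, p.j) in seen:
                raise ValueError(f"duplicate pair ({p.i},{p.j})")
            seen.add((p.i, p.j))

    def __len__(self) -> int:
        return len(self.predictions)

    def pairs(self) -> set[tuple[int, int]]:
        return {(p.i, p.j) for p in self.predictions}


@dataclass(frozen=True)
class MsaSummary:
    """Alignment size and effective depth."""

    L: int
    N: int
    nf: float


@dataclass
class SsePrediction:
    """3-state secondary-structure prediction with per-state confidences.

    ``states`` is an H/E/C string of length L; ``conf`` is an (L, 3) array
    of probabilities ordered (C, H, E) as in PSIPRED SS2 files.
    """

    states: str
    conf: np.ndarray

    def __post_init__(self):
        self.conf = np.asarray(self.conf, dtype=float)
        if self.conf.shape != (len(self.states), 3):
            raise ValueError("confidence array shape mismatch")
        if np.any(self.conf < 0) or np.any(self.conf > 1):
            raise ValueError("confidences outside [0, 1]")
        sums = self.conf.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 0.05):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(
                f"state probabilities at residue {bad + 1} sum to {sums[bad]:.3f}"
            )

    def __len__(self) -> int:
        return len(self.states)

    def state_confidence(self) -> np.ndarray:
        """Confidence of the called state per residue."""
        idx = np.array(["CHE".index(s) for s in self.states])
        return self.conf[np.arange(len(self.states)), idx]


# ---------------------------------------------------------------------------
# CASP RR


def parse_rr(path, L: int, predictor_id: str = "") -> ContactMap:
    """Read a CASP RR contact file.

    Accepts the standard 5-column body ``i j d1 d2 conf`` as well as the
    3-column ``i j conf`` dialect; header keywords (PFRMAT, TARGET, MODEL,
    END, REMARK, AUTHOR, METHOD) and plain sequence lines are tolerated.
    Records are canonicalised to j > i; duplicates keep the maximum
    confidence.
    """
    best: dict[tuple[int, int], float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            first = line.split()[0].upper()
            if first in ("PFRMAT", "TARGET", "MODEL", "END", "REMARK",
                         "AUTHOR", "METHOD"):
                continue
            fields = line.split()
            if len(fields) == 1 and fields[0].isalpha():
                continue  # sequence line
            if len(fields) not in (3, 5):
                raise ParseError(f"{path}:{lineno}: expected 3 or 5 columns")
            try:
                i, j = int(fields[0]), int(fields[1])
                conf = float(fields[-1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if i == j:
                raise ParseError(f"{path}:{lineno}: self-contact ({i},{j})")
            if i > j:
                i, j = j, i
            if j > L or i < 1:
                raise ValueError(
                    f"{path}:{lineno}: residue index ({i},{j}) outside 1..{L}"
                )
            if not (0.0 <= conf <= 1.0 and np.isfinite(conf)):
                raise ParseError(f"{path}:{lineno}: confidence {conf} not in [0,1]")
            key = (i, j)
            if key not in best or conf > best[key]:
                best[key] = conf
    preds = [
        ContactPrediction(i, j, c, predictor_id)
        for (i, j), c in sorted(best.items())
    ]
    return ContactMap(L, preds, predictor_id)


def write_rr(cmap: ContactMap, path, sequence: str | None = None) -> None:
    """Write a canonical CASP RR file (sorted pairs, 5 columns)."""
    with open(path, "w") as fh:
        fh.write("PFRMAT RR\n")
        if sequence:
            for k in range(0, len(sequence), 50):
                fh.write(sequence[k:k + 50] + "\n")
        for p in sorted(cmap.predictions, key=lambda p: (p.i, p.j)):
            fh.write(f"{p.i} {p.j} 0 8 {p.confidence:.6f}\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# alignments and Nf


def read_alignment(path) -> list[str]:
    """Read an aligned FASTA or A3M file into uppercase rows.

    A3M lowercase letters mark insertions relative to the query and are
    dropped, so all returned rows share the query's length.
    """
    rows: list[str] = []
    seq: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if seq:
                    rows.append("".join(seq))
                    seq = []
                continue
            seq.append("".join(c for c in line if not c.islower()))
    if seq:
        rows.append("".join(seq))
    if not rows:
        raise ParseError(f"{path}: no sequences")
    return rows


def compute_nf(msa: list[str], identity_threshold: float = 0.8) -> MsaSummary:
    """Effective number of sequences of an alignment.

    Nf = (1/√L) · Σ_n 1/(1 + m_n) where m_n counts the *other* rows with
    ≥80% identity to row n, identity being measured over columns where
    both rows are non-gap.  Row pairs sharing fewer than L/2 mutually
    aligned columns are treated as non-neighbours.
    """
    if not msa:
        raise ValueError("empty MSA")
    L = len(msa[0])
    if L == 0:
        raise ValueError("zero-length alignment")
    if any(len(row) != L for row in msa):
        raise ValueError("alignment rows have unequal lengths")
    arr = np.array([[ord(c) for c in row.upper()] for row in msa], dtype=np.int16)
    gap = (arr == ord("-")) | (arr == ord("."))
    nongap = ~gap
    N = len(msa)
    m = np.zeros(N, dtype=int)
    for a in range(N):
        both = nongap[a] & nongap
        aligned = both.sum(axis=1)
        matches = ((arr[a] == arr) & both).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ident = np.where(aligned > 0, matches / np.maximum(aligned, 1), 0.0)
        neighbour = (ident >= identity_threshold) & (aligned >= 0.5 * L)
        neighbour[a] = False
        m[a] = int(neighbour.sum())
    nf = float(np.sum(1.0 / (1.0 + m)) / np.sqrt(L))
    return MsaSummary(L=L, N=N, nf=nf)


# ---------------------------------------------------------------------------
# PSIPRED SS2


def parse_ss2(path) -> SsePrediction:
    """Read a PSIPRED vertical-format SS2 file."""
    states: list[str] = []
    conf: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 6:
                raise ParseError(f"{path}:{lineno}: expected 6 columns")
            state = fields[2]
            if state not in "CHE":
                raise ParseError(f"{path}:{lineno}: bad state {state!r}")
            try:
                probs = [float(x) for x in fields[3:6]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            states.append(state)
            conf.append(probs)
    if not states:
        raise ParseError(f"{path}: no residues")
    return SsePrediction("".join(states), np.array(conf))


def write_ss2(sse: SsePrediction, sequence: str, path) -> None:
    with open(path, "w") as fh:
        fh.write("# PSIPRED VFORMAT\n\n")
        for k, (aa, st) in enumerate(zip(sequence, sse.states)):
            c, h, e = sse.conf[k]
            fh.write(f"{k + 1:4d} {aa} {st}  {c:6.3f} {h:6.3f} {e:6.3f}\n")


# ---------------------------------------------------------------------------
# PDB structures


def read_structure(path) -> CoarseStructure:
    """Read a single-chain Cα(+Cβ) trace from a PDB file.

    Every residue must carry a Cα atom; insertion codes are unsupported.
    Residue numbering from the file is preserved.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0 or len(st[0]) == 0:
        raise ParseError(f"{path}: no model/chain")
    chain = st[0][0]
    seq, coords, resnums = [], [], []
    cb, have_cb = [], True
    for res in chain:
        if res.seqid.icode not in ("", " "):
            raise ParseError(
                f"{path}: insertion code at residue {res.seqid.num} unsupported"
            )
        ca = res.find_atom("CA", "*")
        if ca is None:
            raise ParseError(f"{path}: residue {res.seqid.num} lacks a CA atom")
        seq.append(AA3TO1.get(res.name, "X"))
        coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
        resnums.append(res.seqid.num)
        cbat = res.find_atom("CB", "*")
        if cbat is None:
            have_cb = False
        else:
            cb.append([cbat.pos.x, cbat.pos.y, cbat.pos.z])
    return CoarseStructure(
        "".join(seq),
        np.array(coords, dtype=float),
        resnums=np.array(resnums),
        cb_coords=np.array(cb) if have_cb and cb else None,
        name=Path(str(path)).stem,
    )


def write_structure(s: CoarseStructure, path) -> None:
    """Write the Cα trace (and stored Cβ, if any) as a chain-A PDB file."""
    st = gemmi.Structure()
    st.name = s.name or "model"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for k, aa in enumerate(s.sequence):
        res = gemmi.Residue()
        res.name = AA1TO3.get(aa, "UNK")
        res.seqid = gemmi.SeqId(int(s.resnums[k]), " ")
        ca = gemmi.Atom()
        ca.name = "CA"
        ca.element = gemmi.Element("C")
        ca.pos = gemmi.Position(*s.coords[k])
        res.add_atom(ca)
        if s.cb_coords is not None:
            cb = gemmi.Atom()
            cb.name = "CB"
            cb.element = gemmi.Element("C")
            cb.pos = gemmi.Position(*s.cb_coords[k])
            res.add_atom(cb)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    with open(path, "w") as fh:
        fh.write(doc)


def read_fasta(path) -> tuple[str, str]:
    """First record of a FASTA file as (name, sequence)."""
    name, seq = "", []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if seq:
                    break
                name = line[1:].split()[0] if len(line) > 1 else ""
                continue
            seq.append(line)
    if not seq:
        raise ParseError(f"{path}: no sequence")
    return name, "".join(seq)


def write_fasta(name: str, sequence: str, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for k in range(0, len(sequence), 60):
            fh.write(sequence[k:k + 60] + "\n")
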