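"""Library design: building-block registries, barcode codebooks, enumeration.

A single-stranded DNA-encoded library (DEL) built on a glutamic-acid scaffold
couples two diversity sets: building blocks A (amines, acylated onto the
scaffold in step 1) and building blocks B (carboxylic acids or terminal
alkynes, installed in step 2).  Each block carries a dedicated DNA barcode
(CodeA, CodeB); the two stereoisomers of the scaffold are pooled 1:1 and share
one code pair, so chirality is resolved only at hit validation, never at the
sequencing level.  All sequencing analytics therefore live on the
``|A| x |B|`` code-pair grid while the chemical library itself has
``|stereo| x |A| x |B|`` members.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("deldeck")

# chemistry categories for the two diversity sets
A_CLASSES = ("primary-amine", "secondary-amine", "heteroaromatic-amine", "ammonia-control")
B_CLASSES = ("carboxylic-acid", "alkyne")

DNA_ALPHABET = "ACGT"

#: default mass corrections (g/mol) applied when block B is attached:
#: amide condensation loses water; azide-alkyne cycloaddition is additive.
DEFAULT_LINKAGE_DELTAS = {"carboxylic-acid": -18.011, "alkyne": 0.0}


class ManifestError(ValueError):
    """Raised when a library design manifest violates its invariants."""


@dataclass(frozen=True)
class BuildingBlock:
    """One chemical building block with its optional property contributions."""

    block_id: str
    set_label: str  # "A" or "B"
    chem_class: str
    mass: Optional[float] = None
    hbd: Optional[int] = None
    hba: Optional[int] = None
    logp_contrib: Optional[float] = None

    def __post_init__(self) -> None:
        if self.set_label not in ("A", "B"):
            raise ManifestError(f"set_label must be 'A' or 'B', got {self.set_label!r}")
        allowed = A_CLASSES if self.set_label == "A" else B_CLASSES
        if self.chem_class not in allowed:
            raise ManifestError(
                f"chem_class {self.chem_class!r} invalid for set {self.set_label}: "
                f"allowed {allowed}"
            )


@dataclass(frozen=True)
class CodeOligo:
    """A DNA barcode assigned to one building block."""

    code_id: str
    sequence: str
    role: str  # "CodeA" or "CodeB"

    def __post_init__(self) -> None:
        if self.role not in ("CodeA", "CodeB"):
            raise ManifestError(f"role must be CodeA/CodeB, got {self.role!r}")
        if not self.sequence or any(b not in DNA_ALPHABET for b in self.sequence):
            raise ManifestError(
                f"code {self.code_id}: sequence must be non-empty over ACGT, "
                f"got {self.sequence!r}"
            )


@dataclass(frozen=True)
class LibraryMember:
    """One encoded compound: a (stereo, A, B) triple.

    Both stereoisomers map to the same (CodeA, CodeB) pair.
    """

    stereo: str
    a_id: str
    b_id: str
    code_pair: tuple[str, str]


@dataclass(frozen=True)
class PropertyRecord:
    """Computed molecular properties and Lipinski rule-of-five verdict."""

    stereo: str
    a_id: str
    b_id: str
    mw: float
    hbd: int
    hba: int
    logp: float
    ro5_pass: bool


def hamming(s1: str, s2: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(s1) != len(s2):
        raise ValueError("Hamming distance requires equal lengths")
    return sum(a != b for a, b in zip(s1, s2))


@dataclass
class DesignManifest:
    """Full library definition: blocks, stereo labels and barcode codebooks."""

    blocks_a: list[BuildingBlock]
    blocks_b: list[BuildingBlock]
    codebook_a: list[CodeOligo]
    codebook_b: list[CodeOligo]
    stereo_labels: list[str] = field(default_factory=lambda: ["R", "S"])
    scaffold_mass: Optional[float] = None
    linkage_deltas: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LINKAGE_DELTAS)
    )
    d_min: int = 3

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        """Check every manifest invariant; raise ManifestError on violation."""
        for blocks, label in ((self.blocks_a, "A"), (self.blocks_b, "B")):
            ids = [b.block_id for b in blocks]
            dupes = {i for i in ids if ids.count(i) > 1}
            if dupes:
                raise ManifestError(f"duplicate block_id in set {label}: {sorted(dupes)}")
            for b in blocks:
                if b.set_label != label:
                    raise ManifestError(
                        f"block {b.block_id} has set_label {b.set_label}, expected {label}"
                    )
        if len(self.codebook_a) != len(self.blocks_a):
            raise ManifestError(
                f"codebook_a has {len(self.codebook_a)} codes for "
                f"{len(self.blocks_a)} A blocks"
            )
        if len(self.codebook_b) != len(self.blocks_b):
            raise ManifestError(
                f"codebook_b has {len(self.codebook_b)} codes for "
                f"{len(self.blocks_b)} B blocks"
            )
        if not self.stereo_labels:
            raise ManifestError("stereo_labels must be non-empty")
        for book, role in ((self.codebook_a, "CodeA"), (self.codebook_b, "CodeB")):
            lengths = {len(c.sequence) for c in book}
            if len(lengths) > 1:
                raise ManifestError(f"{role} sequences have mixed lengths {sorted(lengths)}")
            check_codebook_distance(book, self.d_min)

    # -- convenience views ----------------------------------------------

    @property
    def n_members(self) -> int:
        return len(self.stereo_labels) * len(self.blocks_a) * len(self.blocks_b)

    @property
    def n_pairs(self) -> int:
        return len(self.blocks_a) * len(self.blocks_b)

    @property
    def a_ids(self) -> list[str]:
        return [b.block_id for b in self.blocks_a]

    @property
    def b_ids(self) -> list[str]:
        return [b.block_id for b in self.blocks_b]

    @property
    def code_length_a(self) -> int:
        return len(self.codebook_a[0].sequence)

    @property
    def code_length_b(self) -> int:
        return len(self.codebook_b[0].sequence)


def check_codebook_distance(codebook: Sequence[CodeOligo], d_min: int) -> None:
    """Verify pairwise Hamming distance >= d_min; name the offending pair."""
    seqs = [c.sequence for c in codebook]
    if len(set(seqs)) != len(seqs):
        seen: dict[str, str] = {}
        for c in codebook:
            if c.sequence in seen:
                raise ManifestError(
                    f"identical code sequences: {seen[c.sequence]} and {c.code_id}"
                )
            seen[c.sequence] = c.code_id
    if len(codebook) < 2:
        return
    # vectorised pairwise check; fine for codebooks of a few hundred codes
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)
    for i in range(len(seqs)):
        dist = (arr[i + 1 :] != arr[i]).sum(axis=1)
        bad = np.nonzero(dist < d_min)[0]
        if bad.size:
            j = i + 1 + int(bad[0])
            raise ManifestError(
                f"codes {codebook[i].code_id} and {codebook[j].code_id} are at "
                f"Hamming distance {int(dist[bad[0]])} < d_min={d_min}"
            )


# ---------------------------------------------------------------------------
# Manifest I/O (TSV sibling files + design.yaml)
# ---------------------------------------------------------------------------

_BLOCK_COLUMNS = ["block_id", "chem_class", "mass", "hbd", "hba", "logp_contrib"]


def _blocks_to_frame(blocks: Sequence[BuildingBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (b.block_id, b.chem_class, b.mass, b.hbd, b.hba, b.logp_contrib)
            for b in blocks
        ],
        columns=_BLOCK_COLUMNS,
    )


def _frame_to_blocks(df: pd.DataFrame, set_label: str) -> list[BuildingBlock]:
    def opt(v, cast):
        return None if pd.isna(v) else cast(v)

    return [
        BuildingBlock(
            block_id=str(r.block_id),
            set_label=set_label,
            chem_class=str(r.chem_class),
            mass=opt(r.mass, float),
            hbd=opt(r.hbd, int),
            hba=opt(r.hba, int),
            logp_contrib=opt(r.logp_contrib, float),
        )
        for r in df.itertuples(index=False)
    ]


def save_manifest(manifest: DesignManifest, path: str | Path) -> Path:
    """Write a manifest directory: blocks/codebook TSVs plus design.yaml."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _blocks_to_frame(manifest.blocks_a).to_csv(path / "blocks_a.tsv", sep="\t", index=False)
    _blocks_to_frame(manifest.blocks_b).to_csv(path / "blocks_b.tsv", sep="\t", index=False)
    for book, name in ((manifest.codebook_a, "codebook_a"), (manifest.codebook_b, "codebook_b")):
        pd.DataFrame(
            [(c.code_id, c.sequence) for c in book], columns=["code_id", "sequence"]
        ).to_csv(path / f"{name}.tsv", sep="\t", index=False)
    meta = {
        "stereo_labels": list(manifest.stereo_labels),
        "scaffold_mass": manifest.scaffold_mass,
        "linkage_deltas": manifest.linkage_deltas,
        "d_min": manifest.d_min,
        "code_length_a": manifest.code_length_a,
        "code_length_b": manifest.code_length_b,
    }
    (path / "design.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    return path


def load_manifest(path: str | Path) -> DesignManifest:
    """Load and validate a manifest directory written by :func:`save_manifest`.

    Raises ManifestError on any invariant violation (duplicate block ids,
    codebook/block length mismatch, codes closer than d_min).
    """
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"manifest directory not found: {path}")
    meta = yaml.safe_load((path / "design.yaml").read_text())
    blocks_a = _frame_to_blocks(pd.read_csv(path / "blocks_a.tsv", sep="\t"), "A")
    blocks_b = _frame_to_blocks(pd.read_csv(path / "blocks_b.tsv", sep="\t"), "B")

    def read_book(name: str, role: str) -> list[CodeOligo]:
        df = pd.read_csv(path / f"{name}.tsv", sep="\t")
        return [CodeOligo(str(r.code_id), str(r.sequence), role) for r in df.itertuples(index=False)]

    manifest = DesignManifest(
        blocks_a=blocks_a,
        blocks_b=blocks_b,
        codebook_a=read_book("codebook_a", "CodeA"),
        codebook_b=read_book("codebook_b", "CodeB"),
        stereo_labels=[str(s) for s in meta["stereo_labels"]],
        scaffold_mass=meta.get("scaffold_mass"),
        linkage_deltas=dict(meta.get("linkage_deltas") or DEFAULT_LINKAGE_DELTAS),
        d_min=int(meta.get("d_min", 3)),
    )
    logger.info(
        "loaded manifest %s: %d A blocks, %d B blocks, %d stereo labels -> %d members",
        path,
        len(manifest.blocks_a),
        len(manifest.blocks_b),
        len(manifest.stereo_labels),
        manifest.n_members,
    )
    return manifest


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------

def enumerate_library(manifest: DesignManifest) -> Iterator[LibraryMember]:
    """Yield every library member in deterministic stereo-major order.

    Yields ``|stereo| * |A| * |B|`` members; the code pair depends only on
    (a_id, b_id), so stereoisomers collapse onto ``|A| * |B|`` distinct pairs.
    """
    code_a = {b.block_id: c.code_id for b, c in zip(manifest.blocks_a, manifest.codebook_a)}
    code_b = {b.block_id: c.code_id for b, c in zip(manifest.blocks_b, manifest.codebook_b)}
    for stereo, a, b in itertools.product(
        manifest.stereo_labels, manifest.blocks_a, manifest.blocks_b
    ):
        yield LibraryMember(
            stereo=stereo,
            a_id=a.block_id,
            b_id=b.block_id,
            code_pair=(code_a[a.block_id], code_b[b.block_id]),
        )


# ---------------------------------------------------------------------------
# Codebook generation
# ---------------------------------------------------------------------------

class CodebookGenerationError(RuntimeError):
    """Raised when the random search cannot place the requested codes."""


def generate_codebook(
    n_codes: int,
    length: int,
    d_min: int,
    seed: int,
    role: str = "CodeA",
    prefix: str = "C",
    attempt_budget: int = 200_000,
) -> list[CodeOligo]:
    """Randomised greedy construction of a barcode set with minimum distance.

    Draws random sequences and keeps each one whose Hamming distance to all
    accepted codes is >= d_min.  Reproducible for a fixed seed.  With the
    default 8-nt codes and d_min=3 any practical DEL codebook (hundreds of
    codes) is found in well under the attempt budget.
    """
    if n_codes < 1:
        raise ValueError("n_codes must be >= 1")
    if d_min > length:
        raise CodebookGenerationError(
            f"d_min={d_min} impossible for length {length}; use longer codes"
        )
    rng = np.random.default_rng(seed)
    accepted = np.empty((0, length), dtype=np.uint8)
    alphabet = np.frombuffer(DNA_ALPHABET.encode(), dtype=np.uint8)
    attempts = 0
    while accepted.shape[0] < n_codes:
        if attempts >= attempt_budget:
            raise CodebookGenerationError(
                f"placed only {accepted.shape[0]}/{n_codes} codes of length {length} "
                f"at d_min={d_min} within {attempt_budget} attempts; "
                "use longer codes or a smaller d_min"
            )
        attempts += 1
        cand = alphabet[rng.integers(0, 4, size=length)]
        if accepted.shape[0] == 0 or ((accepted != cand).sum(axis=1) >= d_min).all():
            accepted = np.vstack([accepted, cand])
    seqs = [row.tobytes().decode() for row in accepted]
    return [CodeOligo(f"{prefix}{i + 1}", s, role) for i, s in enumerate(seqs)]


# ---------------------------------------------------------------------------
# Property annotation (Lipinski rule of five)
# ---------------------------------------------------------------------------

def ro5_pass(mw: float, hbd: int, hba: int, logp: float) -> bool:
    """Lipinski rule of five with inclusive bounds: MW<=500, HBD<=5, HBA<=10, logP<=5."""
    return mw <= 500.0 and hbd <= 5 and hba <= 10 and logp <= 5.0


def annotate_properties(manifest: DesignManifest) -> list[PropertyRecord]:
    """Compute per-member molecular properties and rule-of-five compliance.

    MW = scaffold + mass(A) + mass(B) + linkage delta for B's chemistry;
    HBD/HBA/logP are additive over the block contributions.  Raises if block
    masses are present but scaffold_mass is not.
    """
    have_masses = any(b.mass is not None for b in manifest.blocks_a + manifest.blocks_b)
    if have_masses and manifest.scaffold_mass is None:
        raise ManifestError("block masses provided but scaffold_mass missing")
    if not have_masses:
        raise ManifestError("no block masses provided; property annotation unavailable")

    a_by_id = {b.block_id: b for b in manifest.blocks_a}
    b_by_id = {b.block_id: b for b in manifest.blocks_b}
    records = []
    for m in enumerate_library(manifest):
        a, b = a_by_id[m.a_id], b_by_id[m.b_id]
        if None in (a.mass, b.mass, a.hbd, b.hbd, a.hba, b.hba, a.logp_contrib, b.logp_contrib):
            raise ManifestError(f"incomplete properties for member {m.a_id}/{m.b_id}")
        delta = manifest.linkage_deltas.get(b.chem_class, 0.0)
        mw = manifest.scaffold_mass + a.mass + b.mass + delta
        hbd = a.hbd + b.hbd
        hba = a.hba + b.hba
        logp = a.logp_contrib + b.logp_contrib
        records.append(
            PropertyRecord(
                stereo=m.stereo,
                a_id=m.a_id,
                b_id=m.b_id,
                mw=mw,
                hbd=hbd,
                hba=hba,
                logp=logp,
                ro5_pass=ro5_pass(mw, hbd, hba, logp),
            )
        )
    return records


# ---------------------------------------------------------------------------
# The reference library shape (2 stereoisomers x 300 A x 611 B)
# ---------------------------------------------------------------------------

def reference_manifest(
    seed: int = 0,
    code_length: int = 8,
    d_min: int = 3,
    with_properties: bool = True,
) -> DesignManifest:
    """Build a manifest with the published glutamate-DEL composition.

    Set A: 300 codes = 191 primary amines + 36 secondary amines + 72
    heteroaromatic amines + 1 ammonia control.  Set B: 611 codes = 480
    carboxylic acids + 131 terminal alkynes.  Two stereoisomers (R/S) share
    each code pair, giving 2 x 300 x 611 = 366,600 members on a 183,300-cell
    code-pair grid.  Barcode sequences and (optional) property contributions
    are synthetic: the published design discloses neither oligo sequences nor
    per-block structures, so realistic stand-ins are generated from the seed.
    """
    rng = np.random.default_rng(seed)
    a_classes = (
        ["primary-amine"] * 191 + ["secondary-amine"] * 36
        + ["heteroaromatic-amine"] * 72 + ["ammonia-control"]
    )
    b_classes = ["carboxylic-acid"] * 480 + ["alkyne"] * 131

    def make_blocks(classes: list[str], set_label: str) -> list[BuildingBlock]:
        blocks = []
        for i, cls in enumerate(classes):
            bid = f"{set_label}{i + 1}"
            if not with_properties:
                blocks.append(BuildingBlock(bid, set_label, cls))
                continue
            if cls == "ammonia-control":
                mass, hbd, hba, logp = 17.03, 1, 1, -0.7
            elif set_label == "A":
                mass = float(np.clip(rng.normal(115.0, 35.0), 45.0, 280.0))
                hbd, hba = int(rng.integers(0, 3)), int(rng.integers(0, 4))
                logp = float(rng.normal(0.8, 0.9))
            else:
                mass = float(np.clip(rng.normal(150.0, 45.0), 46.0, 320.0))
                hbd, hba = int(rng.integers(0, 3)), int(rng.integers(1, 5))
                logp = float(rng.normal(1.0, 1.0))
            blocks.append(BuildingBlock(bid, set_label, cls, round(mass, 2), hbd, hba, round(logp, 2)))
        return blocks

    blocks_a = make_blocks(a_classes, "A")
    blocks_b = make_blocks(b_classes, "B")
    codebook_a = generate_codebook(300, code_length, d_min, seed=seed, role="CodeA", prefix="A")
    codebook_b = generate_codebook(611, code_length, d_min, seed=seed + 1, role="CodeB", prefix="B")
    return DesignManifest(
        blocks_a=blocks_a,
        blocks_b=blocks_b,
        codebook_a=codebook_a,
        codebook_b=codebook_b,
        stereo_labels=["R", "S"],
        scaffold_mass=231.2 if with_properties else None,
        d_min=d_min,
    )
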