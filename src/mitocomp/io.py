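"""Reading and writing annotated mitogenomes.

GenBank flat files are the primary interchange format (single circular
record per file).  A bare FASTA plus a TSV feature table is accepted as
an alternative annotation source.  GenBank 1-based inclusive coordinates
are converted to the package's internal 0-based half-open convention on
read and back again on write; ``join()`` locations that cross the
circular origin map to a single feature with ``wraps_origin=True``.
"""

from __future__ import annotations

import csv
import warnings
from importlib import resources
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .model import CANONICAL_GENE_ORDER, GeneFeature, Mitogenome

__all__ = [
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "read_feature_table",
    "write_feature_table",
    "load_gene_synonyms",
    "normalize_gene_name",
]

_KNOWN_NAMES = {name for name, _, _ in CANONICAL_GENE_ORDER}
_GB_TYPE_MAP = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}


def _load_packaged_tsv(name: str) -> list[list[str]]:
    text = (resources.files("mitocomp") / "data" / name).read_text()
    rows = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


def load_gene_synonyms() -> dict[str, str]:
    """Alias -> canonical gene symbol map (aliases matched case-insensitively)."""
    return {alias.upper(): canonical for alias, canonical in _load_packaged_tsv("gene_synonyms.tsv")}


_SYNONYMS: dict[str, str] | None = None


def normalize_gene_name(raw: str) -> str:
    """Map a submitter's gene label onto the canonical symbol set.

    Unknown labels are returned stripped but otherwise untouched; tRNA
    labels are canonicalized to ``tRNA-Xxx`` capitalization.
    """
    global _SYNONYMS
    if _SYNONYMS is None:
        _SYNONYMS = load_gene_synonyms()
    name = raw.strip()
    upper = name.upper()
    if upper in _SYNONYMS:
        return _SYNONYMS[upper]
    for known in _KNOWN_NAMES:
        if upper == known.upper():
            return known
    if upper.startswith("TRNA-") or upper.startswith("TRN"):
        # tRNA-ala -> tRNA-Ala
        body = name.split("-", 1)[1] if "-" in name else name[3:]
        return "tRNA-" + body[:1].upper() + body[1:]
    return name


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

def read_genbank(path: str | Path) -> Mitogenome:
    """Parse a single-record GenBank flat file into a :class:`Mitogenome`.

    Feature names are normalized through the synonym table; features with
    names outside the canonical vocabulary keep their name but are loaded
    with ``ftype='noncoding'`` and a warning.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise ValueError(f"{path}: malformed GenBank record: {exc}") from exc
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one record, found {len(records)}")
    rec = records[0]
    genome = Mitogenome(id=rec.id or rec.name, sequence=str(rec.seq))
    n = genome.length_bp
    for feat in rec.features:
        if feat.type == "source":
            continue
        if feat.type not in ("CDS", "tRNA", "rRNA", "D-loop", "rep_origin", "misc_feature"):
            continue
        name = _feature_name(feat)
        name = normalize_gene_name(name)
        if feat.type == "D-loop" or name == "CR":
            name, ftype = "CR", "noncoding"
        elif feat.type == "rep_origin" or name == "OL":
            name, ftype = "OL", "noncoding"
        elif feat.type in _GB_TYPE_MAP:
            ftype = _GB_TYPE_MAP[feat.type]
            if name not in _KNOWN_NAMES and not name.startswith("tRNA-"):
                warnings.warn(f"{path}: unknown feature name {name!r}; loading as noncoding")
                ftype = "noncoding"
        else:
            ftype = "noncoding"
        start, end, wraps = _location_to_internal(feat.location, n, name)
        strand = "L" if feat.location.strand == -1 else "H"
        anticodon = ""
        if ftype == "tRNA":
            anticodon = _anticodon_from_qualifiers(feat)
        genome.features.append(
            GeneFeature(name=name, ftype=ftype, start=start, end=end,
                        strand=strand, anticodon=anticodon, wraps_origin=wraps))
    genome.sort_features()
    return genome


def _feature_name(feat: SeqFeature) -> str:
    for key in ("gene", "product", "standard_name", "note"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return feat.type


def _anticodon_from_qualifiers(feat: SeqFeature) -> str:
    q = feat.qualifiers.get("anticodon", [""])[0]
    # accept either a bare triplet or the GenBank "(pos:..,aa:Xxx,seq:nnn)" form
    if "seq:" in q:
        q = q.split("seq:")[1].rstrip(")")
    q = q.strip().upper().replace("T", "U")
    return q if len(q) == 3 else ""


def _location_to_internal(loc, genome_length: int, name: str) -> tuple[int, int, bool]:
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        if len(parts) == 2 and int(parts[1].end) == genome_length and int(parts[0].start) == 0:
            # join(X..L, 1..Y): feature crosses the circular origin
            return int(parts[1].start), int(parts[0].end), True
        raise ValueError(f"feature {name!r}: unsupported compound location {loc}")
    return int(loc.start), int(loc.end), False


def write_genbank(genome: Mitogenome, path: str | Path) -> None:
    """Serialize a :class:`Mitogenome` to a single circular GenBank record."""
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, name=genome.id[:16].replace(" ", "_"),
                    description="mitochondrial genome, complete sequence")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular"
    n = genome.length_bp
    for f in genome.features:
        strand = -1 if f.strand == "L" else 1
        if f.wraps_origin:
            loc = CompoundLocation([
                SimpleLocation(f.start, n, strand=strand),
                SimpleLocation(0, f.end, strand=strand),
            ])
        else:
            loc = SimpleLocation(f.start, f.end, strand=strand)
        if f.ftype in ("CDS", "tRNA", "rRNA"):
            gbtype = f.ftype
        elif f.name == "CR":
            gbtype = "D-loop"
        elif f.name == "OL":
            gbtype = "rep_origin"
        else:
            gbtype = "misc_feature"
        quals: dict[str, list[str]] = {"gene": [f.name]}
        if f.anticodon:
            quals["anticodon"] = [f.anticodon]
        rec.features.append(SeqFeature(loc, type=gbtype, qualifiers=quals))
    SeqIO.write([rec], str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA + TSV feature table
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Mitogenome:
    """Read a bare (unannotated) genome from a single-record FASTA."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one FASTA record, found {len(records)}")
    return Mitogenome(id=records[0].id, sequence=str(records[0].seq))


def write_fasta(genome: Mitogenome, path: str | Path) -> None:
    SeqIO.write([SeqRecord(Seq(genome.sequence), id=genome.id, description="")], str(path), "fasta")


_TABLE_COLUMNS = ["name", "ftype", "start_1based", "end_1based", "strand", "anticodon"]


def read_feature_table(path: str | Path, genome: Mitogenome) -> Mitogenome:
    """Attach features from a TSV table (1-based inclusive coordinates).

    A row whose end precedes its start is interpreted as wrapping the
    circular origin.  Returns a new annotated genome.
    """
    out = genome.copy()
    out.features = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t")
        for row in reader:
            start1, end1 = int(row["start_1based"]), int(row["end_1based"])
            wraps = end1 < start1
            out.features.append(GeneFeature(
                name=normalize_gene_name(row["name"]),
                ftype=row["ftype"],
                start=start1 - 1,
                end=end1,  # 1-based inclusive end == 0-based half-open end
                strand=row["strand"],
                anticodon=(row.get("anticodon") or "").strip(),
                wraps_origin=wraps,
            ))
    out.sort_features()
    return out


def write_feature_table(genome: Mitogenome, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TABLE_COLUMNS)
        for f in genome.features:
            writer.writerow([f.name, f.ftype, f.start + 1, f.end, f.strand, f.anticodon])
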