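"""Somatic mutation catalogs: table readers, consequence calls and trinucleotide signatures.

The 96-channel mutational signature follows the standard pyrimidine-centered
convention: every single-base substitution is collapsed onto its pyrimidine
strand, giving six substitution classes (C>A, C>G, C>T, T>A, T>C, T>G), each
observed in 16 trinucleotide contexts (4 possible 5' bases x 4 possible 3'
bases).  Channel index = class * 16 + five_prime * 4 + three_prime with bases
ordered A, C, G, T.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_CLASS_INDEX = {c: i for i, c in enumerate(SUBSTITUTION_CLASSES)}
N_CHANNELS = 96

CONSEQUENCES = ("synonymous", "missense", "nonsense", "other")

# 64-entry codon -> amino acid lookup (standard genetic code), indexed by
# 16*b0 + 4*b1 + b2 with A,C,G,T -> 0..3.  Stops encoded as '*'.
_CODON_AA = np.empty(64, dtype="<U1")
for _i, _b0 in enumerate(BASES):
    for _j, _b1 in enumerate(BASES):
        for _k, _b2 in enumerate(BASES):
            _codon = _b0 + _b1 + _b2
            _CODON_AA[16 * _i + 4 * _j + _k] = standard_dna_table.forward_table.get(
                _codon, "*"
            )


class ReferenceMismatchError(ValueError):
    """The stated reference base does not match the coding sequence."""


class FlankError(ValueError):
    """A trinucleotide context was requested at a CDS end with no flank base."""


@dataclass(frozen=True)
class MutationRecord:
    """One observed somatic substitution."""

    gene: str
    sample_id: str
    tissue: str = ""
    cds_position: int | None = None  # 1-based index into the CDS
    ref_base: str | None = None
    alt_base: str | None = None
    protein_change: str = ""  # e.g. "V310M"; "A12=" for synonymous
    consequence: str = ""  # one of CONSEQUENCES

    def aa_key(self) -> tuple[int, str, str]:
        """(protein position, ref aa, alt aa) parsed from protein_change."""
        m = re.fullmatch(r"([A-Z*])(\d+)([A-Z*=])", self.protein_change)
        if not m:
            raise ValueError(f"unparseable protein change {self.protein_change!r}")
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        if alt == "=":
            alt = ref
        return pos, ref, alt


@dataclass(frozen=True)
class CodingGene:
    """A coding sequence plus one context base beyond each end."""

    gene: str
    cds: str
    flank5: str | None = None
    flank3: str | None = None

    def __post_init__(self):
        cds = self.cds.upper()
        object.__setattr__(self, "cds", cds)
        if not cds or set(cds) - set(BASES):
            raise ValueError(f"{self.gene}: CDS must be non-empty ACGT")
        if len(cds) % 3:
            raise ValueError(f"{self.gene}: CDS length {len(cds)} not divisible by 3")
        aa = translate_cds(cds)
        if "*" in aa[:-1]:
            raise ValueError(f"{self.gene}: internal stop codon")
        for name in ("flank5", "flank3"):
            fl = getattr(self, name)
            if fl is not None and fl not in BASES:
                raise ValueError(f"{self.gene}: {name} must be a single ACGT base")

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3

    def codon(self, aa_position: int) -> str:
        return self.cds[3 * (aa_position - 1) : 3 * aa_position]


def translate_cds(cds: str) -> str:
    """Translate an in-frame nucleotide string with the standard code."""
    idx = np.array([_BASE_INDEX[b] for b in cds], dtype=np.int64)
    codons = idx[0::3] * 16 + idx[1::3] * 4 + idx[2::3]
    return "".join(_CODON_AA[codons])


def classify_consequence(
    gene: CodingGene, cds_position: int, ref_base: str, alt_base: str
) -> tuple[str, str]:
    """Classify a CDS substitution by translating its codon before and after.

    Returns ``(consequence, protein_change)`` where protein_change uses
    one-letter amino acids with 1-based positions ("A2V", nonsense "Q10*",
    synonymous "A2=").  A loss of the terminal stop codon is "other".
    """
    if not 1 <= cds_position <= len(gene.cds):
        raise IndexError(f"cds_position {cds_position} outside CDS of {gene.gene}")
    if ref_base == alt_base:
        raise ValueError("ref_base equals alt_base")
    if gene.cds[cds_position - 1] != ref_base:
        raise ReferenceMismatchError(
            f"{gene.gene} position {cds_position}: CDS has "
            f"{gene.cds[cds_position - 1]}, record says {ref_base}"
        )
    aa_pos = (cds_position - 1) // 3 + 1
    offset = (cds_position - 1) % 3
    old_codon = gene.codon(aa_pos)
    new_codon = old_codon[:offset] + alt_base + old_codon[offset + 1 :]
    old_aa = translate_cds(old_codon)
    new_aa = translate_cds(new_codon)
    if old_aa == new_aa:
        return "synonymous", f"{old_aa}{aa_pos}="
    if new_aa == "*":
        return "nonsense", f"{old_aa}{aa_pos}*"
    if old_aa == "*":  # stop-loss
        return "other", f"*{aa_pos}{new_aa}"
    return "missense", f"{old_aa}{aa_pos}{new_aa}"


def trinucleotide_context(
    gene: CodingGene, cds_position: int, ref_base: str, alt_base: str
) -> int:
    """Map a substitution to its 0-95 pyrimidine-centered channel index."""
    if not 1 <= cds_position <= len(gene.cds):
        raise IndexError(f"cds_position {cds_position} outside CDS")
    if gene.cds[cds_position - 1] != ref_base:
        raise ReferenceMismatchError(
            f"position {cds_position}: CDS has {gene.cds[cds_position - 1]}"
        )
    if cds_position == 1:
        if gene.flank5 is None:
            raise FlankError("no 5' flank base for position 1")
        five = gene.flank5
    else:
        five = gene.cds[cds_position - 2]
    if cds_position == len(gene.cds):
        if gene.flank3 is None:
            raise FlankError("no 3' flank base for the final position")
        three = gene.flank3
    else:
        three = gene.cds[cds_position]
    return context_channel(five, ref_base, alt_base, three)


def context_channel(five: str, ref: str, alt: str, three: str) -> int:
    """Channel index of a raw (possibly purine-centered) substitution context."""
    if ref in "AG":  # collapse onto the pyrimidine strand
        five, ref, alt, three = (
            _COMPLEMENT[three],
            _COMPLEMENT[ref],
            _COMPLEMENT[alt],
            _COMPLEMENT[five],
        )
    cls = _CLASS_INDEX[f"{ref}>{alt}"]
    return cls * 16 + _BASE_INDEX[five] * 4 + _BASE_INDEX[three]


def channel_label(channel: int) -> str:
    """Human-readable label such as 'A[C>T]G'."""
    cls, rest = divmod(channel, 16)
    five, three = divmod(rest, 4)
    return f"{BASES[five]}[{SUBSTITUTION_CLASSES[cls]}]{BASES[three]}"


@dataclass(frozen=True)
class MutationalSignature:
    """Normalized probabilities over the 96 substitution-in-context channels."""

    channel_probs: np.ndarray
    pseudocount: float = 0.0

    def __post_init__(self):
        probs = np.asarray(self.channel_probs, dtype=float)
        object.__setattr__(self, "channel_probs", probs)
        if probs.shape != (N_CHANNELS,):
            raise ValueError("signature must have 96 channels")
        if (probs < 0).any():
            raise ValueError("negative channel probability")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"channel probabilities sum to {probs.sum()}, not 1")

    @classmethod
    def uniform(cls) -> "MutationalSignature":
        return cls(np.full(N_CHANNELS, 1.0 / N_CHANNELS))

    @classmethod
    def from_counts(
        cls, counts: np.ndarray, pseudocount: float = 0.0
    ) -> "MutationalSignature":
        counts = np.asarray(counts, dtype=float)
        total = counts.sum() + N_CHANNELS * pseudocount
        if total <= 0:
            raise ValueError("no counts and no pseudocount")
        return cls((counts + pseudocount) / total, pseudocount=pseudocount)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel": np.arange(N_CHANNELS),
                "label": [channel_label(c) for c in range(N_CHANNELS)],
                "probability": self.channel_probs,
            }
        )


def estimate_signature(
    records: Iterable[MutationRecord],
    genes: Mapping[str, CodingGene],
    pseudocount: float = 0.5,
) -> MutationalSignature:
    """Estimate the cohort signature from CDS-context counts.

    Each usable record (known gene, valid CDS substitution) contributes one
    count to its channel; probabilities are (count + pseudocount) /
    (total + 96 * pseudocount).
    """
    counts = np.zeros(N_CHANNELS)
    usable = 0
    for rec in records:
        gene = genes.get(rec.gene)
        if gene is None or rec.cds_position is None:
            continue
        try:
            ch = trinucleotide_context(
                gene, rec.cds_position, rec.ref_base, rec.alt_base
            )
        except (ReferenceMismatchError, FlankError, IndexError):
            continue
        counts[ch] += 1
        usable += 1
    if usable == 0:
        raise ValueError("no usable records to estimate a signature from")
    return MutationalSignature.from_counts(counts, pseudocount=pseudocount)


def substitution_spectrum(records: Iterable[MutationRecord]) -> dict[str, float]:
    """Pyrimidine-collapsed 6-class substitution proportions."""
    counts = dict.fromkeys(SUBSTITUTION_CLASSES, 0)
    n = 0
    for rec in records:
        if rec.ref_base is None or rec.alt_base is None:
            continue
        ref, alt = rec.ref_base, rec.alt_base
        if ref in "AG":
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        counts[f"{ref}>{alt}"] += 1
        n += 1
    if n == 0:
        raise ValueError("no substitution records")
    return {k: v / n for k, v in counts.items()}


# ---------------------------------------------------------------------------
# Vectorized enumeration of every single-nucleotide change of a gene.
# ---------------------------------------------------------------------------

_CONSEQ_CODE = {name: i for i, name in enumerate(CONSEQUENCES)}


def enumerate_snvs(gene: CodingGene) -> pd.DataFrame:
    """All 3L single-nucleotide changes of a CDS with consequence and channel.

    Returns a DataFrame with columns cds_position (1-based), ref_base,
    alt_base, protein_position, ref_aa, alt_aa, consequence, channel.
    Requires both flanks so the terminal positions have a context.
    """
    if gene.flank5 is None or gene.flank3 is None:
        raise FlankError(f"{gene.gene}: flanks required to enumerate contexts")
    L = len(gene.cds)
    seq = np.array([_BASE_INDEX[b] for b in gene.cds], dtype=np.int64)
    padded = np.concatenate(
        ([_BASE_INDEX[gene.flank5]], seq, [_BASE_INDEX[gene.flank3]])
    )
    codons = seq.reshape(-1, 3)
    codon_idx = codons[:, 0] * 16 + codons[:, 1] * 4 + codons[:, 2]
    old_aa = _CODON_AA[codon_idx]

    pos = np.repeat(np.arange(L), 3)  # 0-based CDS position
    ref = np.repeat(seq, 3)
    # the three non-reference bases at each position
    alt_choices = np.array(
        [[b for b in range(4) if b != r] for r in range(4)], dtype=np.int64
    )
    alt = alt_choices[seq].reshape(-1)

    offset = pos % 3
    aa_pos = pos // 3
    place = np.array([16, 4, 1], dtype=np.int64)[offset]
    new_codon_idx = codon_idx[aa_pos] + (alt - ref) * place
    new_aa = _CODON_AA[new_codon_idx]
    ref_aa = old_aa[aa_pos]

    conseq = np.full(pos.shape, _CONSEQ_CODE["missense"], dtype=np.int64)
    conseq[new_aa == ref_aa] = _CONSEQ_CODE["synonymous"]
    conseq[(new_aa == "*") & (ref_aa != "*")] = _CONSEQ_CODE["nonsense"]
    conseq[(ref_aa == "*") & (new_aa != "*")] = _CONSEQ_CODE["other"]

    five = padded[pos]  # padded index pos == CDS position-1 shifted by flank
    three = padded[pos + 2]
    # pyrimidine collapse: ref in {A,G} -> complement and swap flanks
    is_purine = (ref == 0) | (ref == 2)
    comp = np.array([3, 2, 1, 0], dtype=np.int64)  # A<->T, C<->G
    c_five = np.where(is_purine, comp[three], five)
    c_three = np.where(is_purine, comp[five], three)
    c_ref = np.where(is_purine, comp[ref], ref)
    c_alt = np.where(is_purine, comp[alt], alt)
    # class index over pyrimidine ref C(1)/T(3) and three possible alts
    cls_lookup = -np.ones((4, 4), dtype=np.int64)
    for c, name in enumerate(SUBSTITUTION_CLASSES):
        cls_lookup[_BASE_INDEX[name[0]], _BASE_INDEX[name[2]]] = c
    cls = cls_lookup[c_ref, c_alt]
    channel = cls * 16 + c_five * 4 + c_three

    base_arr = np.array(list(BASES))
    return pd.DataFrame(
        {
            "cds_position": pos + 1,
            "ref_base": base_arr[ref],
            "alt_base": base_arr[alt],
            "protein_position": aa_pos + 1,
            "ref_aa": ref_aa,
            "alt_aa": new_aa,
            "consequence": np.array(CONSEQUENCES)[conseq],
            "channel": channel,
        }
    )


# ---------------------------------------------------------------------------
# Table readers
# ---------------------------------------------------------------------------

DIALECTS = ("simple_tsv", "cosmic_export", "maf_like")

_DIALECT_COLUMNS = {
    "simple_tsv": {
        "gene": "gene",
        "cds": None,
        "cds_pos": "cds_pos",
        "ref": "ref",
        "alt": "alt",
        "protein": None,
        "sample": "sample",
        "tissue": "tissue",
    },
    "cosmic_export": {
        "gene": "Gene name",
        "cds": "Mutation CDS",
        "protein": "Mutation AA",
        "sample": "Sample name",
        "tissue": "Primary site",
    },
    "maf_like": {
        "gene": "Hugo_Symbol",
        "cds": "HGVSc",
        "protein": "HGVSp_Short",
        "sample": "Tumor_Sample_Barcode",
        "tissue": None,
    },
}

_CDNA_RE = re.compile(r"c\.(\d+)([ACGT])>([ACGT])$")
_PROT_RE = re.compile(r"(?:p\.)?([A-Z*])(\d+)([A-Z*=])$")


@dataclass
class RejectedRow:
    row: int
    reason: str
    data: dict = field(default_factory=dict)


def read_mutation_table(
    path: str | Path,
    dialect: str = "simple_tsv",
    genes: Mapping[str, CodingGene] | None = None,
) -> tuple[list[MutationRecord], list[RejectedRow]]:
    """Read a delimited mutation table into normalized records.

    Rows whose protein/cDNA change cannot be parsed (e.g. ``p.?``, indels) are
    returned in the rejects list with a reason, never silently dropped.  When
    ``genes`` is given, substitutions are re-classified against the CDS and
    reference mismatches are rejected loudly.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    cols = _DIALECT_COLUMNS[dialect]
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    mandatory = [c for c in (cols["gene"], cols["sample"]) if c]
    if dialect == "simple_tsv":
        mandatory += [cols["cds_pos"], cols["ref"], cols["alt"]]
    else:
        mandatory += [cols["cds"]]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory columns for {dialect}: {missing}")

    records: list[MutationRecord] = []
    rejects: list[RejectedRow] = []
    for i, row in df.iterrows():
        gene = row[cols["gene"]].strip()
        sample = row[cols["sample"]].strip()
        tissue = row[cols["tissue"]].strip() if cols.get("tissue") in df.columns else ""
        if dialect == "simple_tsv":
            try:
                cds_pos = int(row[cols["cds_pos"]])
            except ValueError:
                rejects.append(RejectedRow(i, "non-integer cds_pos", dict(row)))
                continue
            ref, alt = row[cols["ref"]].strip(), row[cols["alt"]].strip()
            prot = row.get("protein_change", "").strip()
        else:
            m = _CDNA_RE.fullmatch(row[cols["cds"]].strip())
            if not m:
                rejects.append(
                    RejectedRow(i, f"unparseable cDNA change {row[cols['cds']]!r}", dict(row))
                )
                continue
            cds_pos, ref, alt = int(m.group(1)), m.group(2), m.group(3)
            prot_raw = row.get(cols["protein"], "").strip()
            pm = _PROT_RE.fullmatch(prot_raw)
            if prot_raw and not pm:
                rejects.append(
                    RejectedRow(i, f"unparseable protein change {prot_raw!r}", dict(row))
                )
                continue
            prot = "".join(pm.groups()) if pm else ""
        if ref not in BASES or alt not in BASES or ref == alt:
            rejects.append(RejectedRow(i, f"invalid substitution {ref}>{alt}", dict(row)))
            continue
        consequence = _consequence_from_protein_change(prot)
        if genes is not None and gene in genes:
            try:
                consequence, prot = classify_consequence(genes[gene], cds_pos, ref, alt)
            except (ReferenceMismatchError, IndexError) as exc:
                rejects.append(RejectedRow(i, str(exc), dict(row)))
                continue
        records.append(
            MutationRecord(
                gene=gene,
                sample_id=sample,
                tissue=tissue,
                cds_position=cds_pos,
                ref_base=ref,
                alt_base=alt,
                protein_change=prot,
                consequence=consequence,
            )
        )
    return records, rejects


def _consequence_from_protein_change(prot: str) -> str:
    m = _PROT_RE.fullmatch(prot)
    if not m:
        return ""
    ref, _, alt = m.groups()
    if alt in ("=", ref):
        return "synonymous"
    if alt == "*":
        return "nonsense"
    if ref == "*":
        return "other"
    return "missense"


def write_simple_tsv(records: Sequence[MutationRecord], path: str | Path) -> None:
    """Write records in the simple_tsv dialect (round-trips with the reader)."""
    df = pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "cds_pos": [r.cds_position for r in records],
            "ref": [r.ref_base for r in records],
            "alt": [r.alt_base for r in records],
            "sample": [r.sample_id for r in records],
            "tissue": [r.tissue for r in records],
            "protein_change": [r.protein_change for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_cds_fasta(path: str | Path) -> dict[str, CodingGene]:
    """Read coding sequences from FASTA.

    Header format ``>GENE [flank5=X] [flank3=Y]``; flanks default to None.
    """
    from Bio import SeqIO

    genes: dict[str, CodingGene] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split()
        kw = dict(p.split("=", 1) for p in parts[1:] if "=" in p)
        genes[rec.id] = CodingGene(
            gene=rec.id,
            cds=str(rec.seq),
            flank5=kw.get("flank5"),
            flank3=kw.get("flank3"),
        )
    return genes


def write_cds_fasta(genes: Mapping[str, CodingGene], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes.values():
            extra = ""
            if g.flank5 is not None:
                extra += f" flank5={g.flank5}"
            if g.flank3 is not None:
                extra += f" flank3={g.flank3}"
            fh.write(f">{g.gene}{extra}\n")
            for i in range(0, len(g.cds), 60):
                fh.write(g.cds[i : i + 60] + "\n")
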