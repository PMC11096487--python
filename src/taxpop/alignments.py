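"""Alignment and sample-map I/O, marker concatenation, haplotype collapsing
and simple indel coding.

Sequences live in memory as plain strings over ``{A, C, G, T, -, N}``.
``N`` is treated as missing data throughout; gap handling is configurable
per operation (see :func:`collapse_haplotypes`).  Coordinates are 0-based
half-open internally; every writer that reports coordinates emits 1-based
inclusive positions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_CHARS = set("ACGT-N")
MISSING = "?"

PHASE_SUFFIXES = ("_h1", "_h2")


class AlignmentError(ValueError):
    """Raised for malformed alignments or sample maps."""


@dataclass
class Alignment:
    """An aligned set of sequences.

    Parameters
    ----------
    records
        ``(sequence_id, sequence)`` pairs, all sequences of equal length.
    ploidy_mode
        ``"haploid"`` (one record per individual, e.g. concatenated cpDNA)
        or ``"diploid_phased"`` (two records per individual carrying the
        phase suffixes ``_h1`` / ``_h2``, e.g. phased ITS).
    """

    records: list[tuple[str, str]]
    ploidy_mode: str = "haploid"
    marker_boundaries: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ploidy_mode not in ("haploid", "diploid_phased"):
            raise AlignmentError(f"unknown ploidy_mode {self.ploidy_mode!r}")
        lengths = {len(s) for _, s in self.records}
        if len(lengths) > 1:
            bad = self._length_offender()
            raise AlignmentError(f"length mismatch: record {bad!r} differs from the rest")
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise AlignmentError(f"duplicate sequence id {dup!r}")
        for rid, seq in self.records:
            extra = set(seq.upper()) - VALID_CHARS
            if extra:
                raise AlignmentError(
                    f"record {rid!r} contains unsupported characters {sorted(extra)}; "
                    "only A,C,G,T,-,N are accepted"
                )
        if self.ploidy_mode == "diploid_phased":
            self._check_phasing()

    def _length_offender(self) -> str:
        ref = len(self.records[0][1])
        for rid, seq in self.records:
            if len(seq) != ref:
                return rid
        return self.records[0][0]

    def _check_phasing(self) -> None:
        seen: dict[str, set[str]] = {}
        for rid, _ in self.records:
            stem, phase = split_phase(rid)
            seen.setdefault(stem, set()).add(phase)
        for stem, phases in seen.items():
            if phases != {"_h1", "_h2"}:
                raise AlignmentError(
                    f"individual {stem!r} must contribute exactly records "
                    f"{stem}_h1 and {stem}_h2; saw phases {sorted(phases)}"
                )

    @property
    def length(self) -> int:
        return len(self.records[0][1]) if self.records else 0

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def individuals(self) -> list[str]:
        """Individual stems, in order of first appearance."""
        out, seen = [], set()
        for rid, _ in self.records:
            stem = split_phase(rid)[0] if self.ploidy_mode == "diploid_phased" else rid
            if stem not in seen:
                seen.add(stem)
                out.append(stem)
        return out


def split_phase(record_id: str) -> tuple[str, str]:
    """Split a phased record id into (individual stem, phase suffix)."""
    for suf in PHASE_SUFFIXES:
        if record_id.endswith(suf):
            return record_id[: -len(suf)], suf
    raise AlignmentError(f"record {record_id!r} lacks a _h1/_h2 phase suffix")


def read_alignment(path, ploidy_mode: str = "haploid") -> Alignment:
    """Read a FASTA alignment, validating equal lengths and unique ids."""
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise AlignmentError(f"no sequences found in {path}")
    return Alignment(records, ploidy_mode=ploidy_mode)


def write_alignment(alignment: Alignment, path) -> None:
    recs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in alignment.records]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


# --------------------------------------------------------------------------
# sample maps

SAMPLE_MAP_COLUMNS = ["sample_id", "population", "taxon", "ploidy"]


def read_sample_map(path) -> pd.DataFrame:
    smap = pd.read_csv(path, sep="\t", dtype=str)
    return validate_sample_map(smap)


def write_sample_map(smap: pd.DataFrame, path) -> None:
    smap[SAMPLE_MAP_COLUMNS].to_csv(path, sep="\t", index=False)


def validate_sample_map(smap: pd.DataFrame) -> pd.DataFrame:
    missing = set(SAMPLE_MAP_COLUMNS) - set(smap.columns)
    if missing:
        raise AlignmentError(f"sample map missing columns {sorted(missing)}")
    if smap["sample_id"].duplicated().any():
        dup = smap.loc[smap["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise AlignmentError(f"duplicate sample_id {dup!r} in sample map")
    return smap.reset_index(drop=True)


def check_alignment_against_map(alignment: Alignment, smap: pd.DataFrame) -> None:
    """Every record's individual stem must appear exactly once in the map."""
    mapped = set(smap["sample_id"])
    for stem in alignment.individuals():
        if stem not in mapped:
            raise AlignmentError(f"individual {stem!r} absent from sample map")


# --------------------------------------------------------------------------
# marker concatenation

def concatenate_markers(alignments: list[Alignment], smap: pd.DataFrame | None = None,
                        names: list[str] | None = None) -> Alignment:
    """Concatenate haploid marker alignments individual-by-individual.

    Marker order is the order given; per-marker column offsets are recorded
    in ``marker_boundaries`` as ``(name, start, end)`` half-open intervals.
    Any individual missing from any marker aborts the concatenation.
    """
    if not alignments:
        raise AlignmentError("no alignments to concatenate")
    for aln in alignments:
        if aln.ploidy_mode != "haploid":
            raise AlignmentError("concatenation requires haploid alignments")
    names = names or [f"marker{i + 1}" for i in range(len(alignments))]
    id_sets = [set(a.ids) for a in alignments]
    universe = set.union(*id_sets)
    for name, ids in zip(names, id_sets):
        absent = universe - ids
        if absent:
            raise AlignmentError(
                f"individual {sorted(absent)[0]!r} missing from marker {name!r}"
            )
    order = alignments[0].ids
    lookup = [dict(a.records) for a in alignments]
    boundaries, offset = [], 0
    for name, aln in zip(names, alignments):
        boundaries.append((name, offset, offset + aln.length))
        offset += aln.length
    records = [(rid, "".join(tbl[rid] for tbl in lookup)) for rid in order]
    out = Alignment(records, ploidy_mode="haploid")
    out.marker_boundaries = boundaries
    if smap is not None:
        check_alignment_against_map(out, smap)
    return out


# --------------------------------------------------------------------------
# simple indel coding


@dataclass
class IndelMatrix:
    """One binary character per distinct contiguous gap run.

    ``events`` are ``(start, end)`` half-open column intervals, sorted;
    ``states`` maps record id -> tuple over events with values ``"1"``
    (the record has exactly that maximal run), ``"0"`` (nucleotides across
    the span) or ``"?"`` (a longer run subsumes the span, so the state is
    unknowable).  Reports print events 1-based inclusive.
    """

    events: list[tuple[int, int]]
    states: dict[str, tuple[str, ...]]

    @property
    def n_characters(self) -> int:
        return len(self.events)

    def events_1based(self) -> list[tuple[int, int]]:
        return [(s + 1, e) for s, e in self.events]


def _gap_runs(seq: str) -> list[tuple[int, int]]:
    runs = []
    for is_gap, grp in itertools.groupby(enumerate(seq), key=lambda t: t[1] == "-"):
        if is_gap:
            grp = list(grp)
            runs.append((grp[0][0], grp[-1][0] + 1))
    return runs


def code_indels_simple(alignment: Alignment) -> IndelMatrix:
    """Recode each distinct contiguous gap run as one presence/absence
    character (simple indel coding).

    A sequence scores ``1`` for a character if one of its maximal gap runs
    is exactly the character's ``(start, end)`` interval, ``?`` if one of
    its runs strictly contains the interval, and ``0`` otherwise.
    """
    per_record = {rid: _gap_runs(seq) for rid, seq in alignment.records}
    events = sorted({run for runs in per_record.values() for run in runs})
    states = {}
    for rid, _ in alignment.records:
        runs = per_record[rid]
        row = []
        for s, e in events:
            if (s, e) in runs:
                row.append("1")
            elif any(rs <= s and e <= re and (rs, re) != (s, e) for rs, re in runs):
                row.append(MISSING)
            else:
                row.append("0")
        states[rid] = tuple(row)
    return IndelMatrix(events, states)


# --------------------------------------------------------------------------
# haplotype collapsing


@dataclass
class HaplotypeTable:
    """Distinct haplotypes with per-population counts.

    ``haplotypes`` maps haplotype id -> representative character tuple
    (bases, optionally followed by indel characters); ``sequences`` maps
    haplotype id -> representative sequence string; ``counts`` is a
    haplotype x population DataFrame; ``assignments`` maps every input
    record id to its haplotype id.
    """

    haplotypes: dict[str, tuple[str, ...]]
    sequences: dict[str, str]
    counts: pd.DataFrame
    assignments: dict[str, str]
    prefix: str = "H"

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def haplotype_ids(self) -> list[str]:
        return list(self.haplotypes)

    def counts_by(self, smap: pd.DataFrame, column: str) -> pd.DataFrame:
        """Haplotype counts cross-tabulated by an arbitrary sample-map
        column (e.g. ``taxon``)."""
        meta = smap.set_index("sample_id")[column]
        rows = []
        for rid, hap in self.assignments.items():
            stem = rid
            for suf in PHASE_SUFFIXES:
                if rid.endswith(suf):
                    stem = rid[: -len(suf)]
                    break
            rows.append((hap, meta.loc[stem]))
        df = pd.DataFrame(rows, columns=["haplotype", column])
        tab = pd.crosstab(df["haplotype"], df[column])
        return tab.reindex(self.haplotype_ids(), fill_value=0)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t")

    def to_fasta(self, path) -> None:
        recs = [SeqRecord(Seq(seq), id=hid, description="") for hid, seq in self.sequences.items()]
        with open(path, "w") as fh:
            SeqIO.write(recs, fh, "fasta")


def _matches(a: tuple[str, ...], b: tuple[str, ...]) -> bool:
    return all(x == y or x == MISSING or y == MISSING for x, y in zip(a, b))


def _merge(a: tuple[str, ...], b: tuple[str, ...]) -> tuple[str, ...]:
    return tuple(y if x == MISSING else x for x, y in zip(a, b))


def collapse_haplotypes(alignment: Alignment, smap: pd.DataFrame | None = None,
                        use_indel_chars: bool = True,
                        gap_as_missing: bool | None = None,
                        prefix: str = "H") -> HaplotypeTable:
    """Collapse identical sequences into haplotypes and tally them per
    population.

    With ``use_indel_chars`` the gap columns are masked to missing in the
    base characters and each coded indel event contributes one extra
    character (a single mutational step downstream).  Without it, gaps are
    kept as a fifth state unless ``gap_as_missing`` forces them to missing.
    ``N`` is always missing.  Missing characters match anything; haplotype
    ids are assigned by first appearance in record order.
    """
    if gap_as_missing is None:
        gap_as_missing = use_indel_chars
    indels = code_indels_simple(alignment) if use_indel_chars else None

    keys: dict[str, tuple[str, ...]] = {}
    for rid, seq in alignment.records:
        chars = []
        for c in seq:
            if c == "N" or (c == "-" and gap_as_missing):
                chars.append(MISSING)
            else:
                chars.append(c)
        if indels is not None:
            chars.extend(indels.states[rid])
        keys[rid] = tuple(chars)

    hap_reps: list[tuple[str, ...]] = []
    hap_first_record: list[str] = []
    assignments: dict[str, str] = {}
    for rid, _ in alignment.records:
        key = keys[rid]
        for i, rep in enumerate(hap_reps):
            if _matches(key, rep):
                hap_reps[i] = _merge(rep, key)
                assignments[rid] = f"{prefix}{i + 1}"
                break
        else:
            hap_reps.append(key)
            hap_first_record.append(rid)
            assignments[rid] = f"{prefix}{len(hap_reps)}"

    hap_ids = [f"{prefix}{i + 1}" for i in range(len(hap_reps))]
    haplotypes = dict(zip(hap_ids, hap_reps))
    seq_lookup = dict(alignment.records)
    sequences = {hid: seq_lookup[rid] for hid, rid in zip(hap_ids, hap_first_record)}

    if smap is not None:
        check_alignment_against_map(alignment, smap)
        pop = smap.set_index("sample_id")["population"]
        rows = []
        for rid in alignment.ids:
            stem = split_phase(rid)[0] if alignment.ploidy_mode == "diploid_phased" else rid
            rows.append((assignments[rid], pop.loc[stem]))
        df = pd.DataFrame(rows, columns=["haplotype", "population"])
        counts = pd.crosstab(df["haplotype"], df["population"]).reindex(hap_ids, fill_value=0)
    else:
        counts = pd.DataFrame(
            {"all": [sum(1 for v in assignments.values() if v == h) for h in hap_ids]},
            index=pd.Index(hap_ids, name="haplotype"),
        )
    return HaplotypeTable(haplotypes, sequences, counts, assignments, prefix=prefix)
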