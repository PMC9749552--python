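"""Species-specific probe selection from a multiple sequence alignment.

The method: slide a fixed-length window (default 31 columns, the length of
the published box-turtle cytb probe) across an MSA of one target species and
one or more nontarget species, count mismatches of every nontarget row
against the target row inside each window, and select the window that
maximises the *minimum* mismatch over nontargets — the window hardest for
any nontarget to hybridise with.  The selected window's ungapped target
subsequence is the capture probe; the full oligo panel (thiolated probe,
reverse-complementary target, k-mismatch variants, noncomplementary
control) is derived from it.

Alignment construction itself (ClustalW/MAFFT/MEGA) is out of scope: this
module consumes an existing alignment in aligned-FASTA or Clustal format.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .oligo import (
    IUPAC_ALPHABET,
    MismatchPolicy,
    Oligo,
    SequenceError,
    STRICT,
    introduce_mismatches,
    percent_mismatch,
    mismatch_count,
    reverse_complement,
    round_percent,
    write_oligo_fasta,
)

logger = logging.getLogger(__name__)

GAP = "-"

#: 5' chemistry applied to the capture probe: thiol anchor for gold
#: coupling plus a six-carbon spacer arm that lifts the probe off the
#: electrode surface.
THIOL_C6 = "HS-S-(CH2)6"


class AlignmentError(ValueError):
    """Raised for malformed alignments or invalid scan parameters."""


@dataclass(frozen=True)
class AlignedSet:
    """An MSA with one designated target species.

    records
        Ordered ``(species_id, gapped_sequence)`` pairs; all sequences the
        same length, characters IUPAC or ``-``.
    target_id
        The species the probe must match 100%.
    co_target_ids
        Optional additional conspecific rows (intraspecies replicates): a
        window is usable only where all target-flagged rows agree, so the
        probe sits in an intraspecies-conserved region.  They are excluded
        from the nontarget mismatch profile.
    """

    records: tuple[tuple[str, str], ...]
    target_id: str
    co_target_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("empty alignment")
        ids = [sid for sid, _ in self.records]
        if len(set(ids)) != len(ids):
            raise AlignmentError("duplicate species ids in alignment")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise AlignmentError(
                f"ragged alignment: sequence lengths {sorted(lengths)} differ"
            )
        if self.target_id not in ids:
            raise AlignmentError(f"target id {self.target_id!r} not in alignment")
        for cid in self.co_target_ids:
            if cid not in ids:
                raise AlignmentError(f"co-target id {cid!r} not in alignment")
        if not self.nontarget_ids:
            raise AlignmentError("alignment has no nontarget records")
        for sid, seq in self.records:
            bad = set(seq) - IUPAC_ALPHABET - {GAP}
            if bad:
                raise AlignmentError(
                    f"record {sid!r} contains non-IUPAC characters {sorted(bad)}"
                )

    @property
    def alignment_length(self) -> int:
        return len(self.records[0][1])

    @property
    def target_row(self) -> str:
        return dict(self.records)[self.target_id]

    @property
    def nontarget_ids(self) -> tuple[str, ...]:
        skip = {self.target_id, *self.co_target_ids}
        return tuple(sid for sid, _ in self.records if sid not in skip)

    def row(self, species_id: str) -> str:
        return dict(self.records)[species_id]

    def ungapped_target_length(self) -> int:
        return sum(1 for c in self.target_row if c != GAP)


def read_alignment(
    path: str | Path,
    target_id: str,
    format: str = "fasta",
    co_target_ids: Sequence[str] = (),
) -> AlignedSet:
    """Read an MSA from aligned FASTA (``fasta``) or Clustal (``clustal``).

    Sequences are upper-cased; ``.`` characters (match-to-first-record
    shorthand) are expanded against the first record.
    """
    from Bio import AlignIO

    fmt = {"fasta": "fasta", "afa": "fasta", "clustal": "clustal", "aln": "clustal"}.get(
        format.lower()
    )
    if fmt is None:
        raise AlignmentError(f"unknown alignment format {format!r}")
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as e:
        raise AlignmentError(f"could not parse {path} as {fmt}: {e}") from e
    rows = [(rec.id, str(rec.seq).upper()) for rec in aln]
    if not rows:
        raise AlignmentError(f"no records in {path}")
    # expand '.'-as-match shorthand against the first record
    first = rows[0][1]
    expanded = [rows[0]]
    for sid, seq in rows[1:]:
        if "." in seq:
            seq = "".join(f if c == "." else c for c, f in zip(seq, first))
        expanded.append((sid, seq))
    return AlignedSet(tuple(expanded), target_id, tuple(co_target_ids))


@dataclass(frozen=True)
class MismatchProfile:
    """Per-nontarget mismatch counts of one alignment window vs the target."""

    per_species: dict[str, tuple[int, float]]  # species -> (count, percent)
    min_mismatch: int
    mean_mismatch: float
    max_mismatch: int

    @classmethod
    def from_counts(
        cls, counts: dict[str, int], denominators: dict[str, int]
    ) -> "MismatchProfile":
        per = {
            sid: (c, 100.0 * c / denominators[sid] if denominators[sid] else 0.0)
            for sid, c in counts.items()
        }
        vals = list(counts.values())
        return cls(per, min(vals), statistics.fmean(vals), max(vals))


@dataclass(frozen=True)
class ProbeCandidate:
    """One alignment window scored against all nontargets.

    ``window_start_col`` is 0-based internally; user-facing reports print
    it 1-based.  ``valid`` is False (with ``reason``) where the target row
    has a gap inside the window — such a window cannot be synthesised as an
    oligo — or where co-target rows disagree.
    """

    window_start_col: int
    window_length: int
    probe_sequence: str
    target_coord_start: int  # 1-based position in the ungapped target
    profile: MismatchProfile | None
    valid: bool
    reason: str = ""


def _window_counts(
    target_win: str,
    other_win: str,
    policy: MismatchPolicy,
) -> tuple[int, int]:
    """(mismatches, compared_columns) for one nontarget row over a window."""
    mm = 0
    compared = 0
    for t, o in zip(target_win, other_win):
        if o == GAP:
            if policy.gap_mode == "exclude":
                continue
            compared += 1
            mm += 1
            continue
        compared += 1
        if not policy.symbols_match(t, o):
            mm += 1
    return mm, compared


def scan_windows(
    msa: AlignedSet,
    window_length: int = 31,
    policy: MismatchPolicy = STRICT,
) -> list[ProbeCandidate]:
    """Score every alignment window of *window_length* columns.

    One candidate per start column, in order.  A window is valid when the
    target row is gap-free across it (exactly *window_length* bases) and,
    in multi-target mode, all target-flagged rows are identical across it.
    For valid windows the per-nontarget mismatch count is computed
    column-wise, with nontarget gap columns handled per ``policy.gap_mode``.
    """
    if window_length < 10:
        raise AlignmentError(f"window_length {window_length} < 10")
    if window_length > msa.ungapped_target_length():
        raise AlignmentError(
            f"window_length {window_length} exceeds ungapped target length "
            f"{msa.ungapped_target_length()}"
        )
    target = msa.target_row
    # 1-based ungapped coordinate of each alignment column's target base
    ungapped_coord = []
    pos = 0
    for c in target:
        if c != GAP:
            pos += 1
        ungapped_coord.append(pos)

    candidates: list[ProbeCandidate] = []
    for start in range(msa.alignment_length - window_length + 1):
        end = start + window_length
        t_win = target[start:end]
        if GAP in t_win:
            candidates.append(
                ProbeCandidate(start, window_length, "", 0, None, False, "target-gap")
            )
            continue
        conflict = next(
            (
                cid
                for cid in msa.co_target_ids
                if msa.row(cid)[start:end] != t_win
            ),
            None,
        )
        if conflict is not None:
            candidates.append(
                ProbeCandidate(
                    start, window_length, "", 0, None, False,
                    f"target-polymorphic vs {conflict}",
                )
            )
            continue
        counts: dict[str, int] = {}
        denoms: dict[str, int] = {}
        for sid in msa.nontarget_ids:
            mm, compared = _window_counts(t_win, msa.row(sid)[start:end], policy)
            counts[sid] = mm
            denoms[sid] = compared
        candidates.append(
            ProbeCandidate(
                start,
                window_length,
                t_win,
                ungapped_coord[start],
                MismatchProfile.from_counts(counts, denoms),
                True,
            )
        )
    return candidates


def select_probe(candidates: Sequence[ProbeCandidate]) -> ProbeCandidate:
    """Pick the valid window maximising the minimum nontarget mismatch.

    Ties break by higher mean mismatch, then leftmost start column — a
    deterministic order, so the result is invariant under permutation of
    the candidate list.  The top-5 ranking is logged.
    """
    valid = [c for c in candidates if c.valid]
    if not valid:
        raise AlignmentError(
            "no valid probe window: every window has a target gap or "
            "target polymorphism; try a shorter window or another region"
        )
    ranked = sorted(
        valid,
        key=lambda c: (-c.profile.min_mismatch, -c.profile.mean_mismatch, c.window_start_col),
    )
    top = ranked[:5]
    logger.info(
        "probe selection top-%d: %s",
        len(top),
        "; ".join(
            f"col {c.window_start_col + 1}: min={c.profile.min_mismatch} "
            f"mean={c.profile.mean_mismatch:.2f} max={c.profile.max_mismatch}"
            for c in top
        ),
    )
    return ranked[0]


# ---------------------------------------------------------------------------
# Oligo panel construction
# ---------------------------------------------------------------------------

#: Transversion partners used for designed mismatches (purine<->pyrimidine
#: swaps destabilise a duplex more reliably than transitions, giving the
#: variant oligos maximal discriminating power per edit).
_TRANSVERSION = {"A": "C", "C": "A", "G": "T", "T": "G"}


@dataclass(frozen=True)
class ProbePanel:
    """The full oligo panel derived from a selected probe window."""

    probe: Oligo
    reverse_complement: Oligo
    variants: tuple[Oligo, ...]
    noncomplementary_control: Oligo

    def all_oligos(self) -> tuple[Oligo, ...]:
        return (self.probe, self.reverse_complement, *self.variants,
                self.noncomplementary_control)


def build_panel(
    selected: ProbeCandidate,
    variant_specs: Sequence[int] = (1, 3),
    seed: int = 0,
    control_min_percent: float = 40.0,
    max_control_attempts: int = 1000,
) -> ProbePanel:
    """Derive the hybridisation test panel from the selected window.

    The probe carries the 5' thiol + C6 spacer annotation; the reverse
    complement is the fully complementary target; each ``k`` in
    *variant_specs* yields an RC variant with exactly k transversion
    mismatches at positions drawn without replacement from a seeded
    generator; the noncomplementary control is a seeded shuffle of the RC
    accepted once its mismatch percent vs the RC reaches
    *control_min_percent* (default 40% of the length).
    """
    if not selected.valid:
        raise AlignmentError(f"cannot build panel from invalid candidate: {selected.reason}")
    rng = np.random.default_rng(seed)
    probe_seq = selected.probe_sequence
    n = len(probe_seq)
    for k in variant_specs:
        if not 0 < k < n:
            raise ValueError(f"variant mismatch count {k} out of range 1..{n - 1}")

    probe = Oligo("probe", probe_seq, five_prime_modifier=THIOL_C6,
                  description="capture probe")
    rc_seq = reverse_complement(probe_seq)
    rc = Oligo("RC", rc_seq, description="reverse complementary target")

    variants = []
    for k in variant_specs:
        positions = rng.choice(n, size=k, replace=False)
        edits = [(int(p) + 1, _TRANSVERSION[rc_seq[p]]) for p in sorted(positions)]
        variants.append(
            Oligo(f"{k}MN", introduce_mismatches(rc_seq, edits),
                  description=f"RC {k}-base mismatch variant")
        )

    control_seq = None
    for _ in range(max_control_attempts):
        shuffled = "".join(rng.permutation(list(rc_seq)))
        if percent_mismatch(rc_seq, shuffled) >= control_min_percent:
            control_seq = shuffled
            break
    if control_seq is None:
        raise AlignmentError(
            f"could not build a noncomplementary control with >= "
            f"{control_min_percent}% mismatch in {max_control_attempts} attempts"
        )
    control = Oligo("NC", control_seq, description="noncomplementary control")
    return ProbePanel(probe, rc, tuple(variants), control)


def write_panel(panel: ProbePanel, path: str | Path) -> None:
    write_oligo_fasta(panel.all_oligos(), path)


# ---------------------------------------------------------------------------
# Specificity report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpecificityReport:
    """Per-species mismatch table for the selected window, plus summary."""

    table: pd.DataFrame
    summary: str

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def to_text(self) -> str:
        """Fixed-width dot-notation rendering: '.' marks a match with the target."""
        width = max(len(s) for s in self.table["species_id"])
        lines = []
        for _, r in self.table.iterrows():
            lines.append(
                f"{r['species_id']:<{width}}  {r['window']}  "
                f"{r['mismatches']:>2d} ({r['percent_rounded']}%)"
            )
        lines.append(self.summary)
        return "\n".join(lines)


def specificity_report(
    msa: AlignedSet,
    selected: ProbeCandidate,
    policy: MismatchPolicy = STRICT,
) -> SpecificityReport:
    """Tabulate every species against the selected probe window.

    The target row shows its own sequence and 100% match; nontarget rows
    use dot notation ('.' = match, letter = mismatching base, '-' = gap).
    The summary line reports the nontarget range in the conventional
    "N–M bases (p–q%)" form.
    """
    if not selected.valid:
        raise AlignmentError("specificity report requires a valid candidate")
    start = selected.window_start_col
    end = start + selected.window_length
    t_win = msa.target_row[start:end]

    rows = []
    rows.append(
        {
            "species_id": msa.target_id,
            "role": "target",
            "window": t_win,
            "mismatches": 0,
            "percent": 0.0,
            "percent_rounded": 0,
            "percent_match": 100.0,
        }
    )
    for sid in msa.nontarget_ids:
        o_win = msa.row(sid)[start:end]
        mm, compared = _window_counts(t_win, o_win, policy)
        dotted = "".join(
            o if o == GAP or not policy.symbols_match(t, o) else "."
            for t, o in zip(t_win, o_win)
        )
        pct = 100.0 * mm / compared if compared else 0.0
        rows.append(
            {
                "species_id": sid,
                "role": "nontarget",
                "window": dotted,
                "mismatches": mm,
                "percent": pct,
                "percent_rounded": round_percent(pct),
                "percent_match": 100.0 - pct,
            }
        )
    table = pd.DataFrame(rows)
    nt = table[table["role"] == "nontarget"]
    lo_c, hi_c = int(nt["mismatches"].min()), int(nt["mismatches"].max())
    lo_p = round_percent(float(nt["percent"].min()))
    hi_p = round_percent(float(nt["percent"].max()))
    summary = (
        f"nontarget mismatches: {lo_c}–{hi_c} bases ({lo_p}–{hi_p}%)"
    )
    return SpecificityReport(table, summary)
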