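"""Primer search engines.

The catalog builder talks to a small engine interface so the thermodynamic
search is pluggable: the built-in engine implemented here (no external
dependency, default) and an optional binding to the external Primer3 library
when it is installed.

The built-in engine scores every candidate oligo in the allowed region by a
Primer3-style penalty

    penalty = w_tm * |Tm - Tm_opt| + w_size * |len - size_opt| + w_gc * |GC - GC_opt|

with duplex melting temperatures from unified nearest-neighbor
thermodynamics (SantaLucia 1998 parameter set, entropic salt correction
0.368 * (N-1) * ln[Na+]), and assembles pairs by ascending

    pair_penalty = left + right + w_tm_diff * |Tm_left - Tm_right|

subject to the hard constraints: product size window, primer length and Tm
and GC windows, maximum homopolymer run, no long self-complementary run
(hairpin / self-dimer proxy), and — in intron-spanning mode — the amplicon
must contain the exon-exon junction.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Protocol

import numpy as np

__all__ = [
    "EngineParams",
    "PairCandidate",
    "PrimerSearchEngine",
    "BuiltinEngine",
    "Primer3Engine",
    "primer_tm",
    "primer_gc",
    "oligo_penalty",
]

R_GAS = 1.987  # cal / (mol K)

# unified nearest-neighbor parameters (dH kcal/mol, dS cal/mol/K)
NN_PARAMS: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
INIT_AT = (2.3, 4.1)
INIT_GC = (0.1, -2.8)

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class EngineParams:
    """Tunables of the primer search, echoed into catalog metadata.

    Optima follow common qPCR practice (a 60 C annealing step, 20-mers,
    50% GC); hard windows are deliberately generous so that ordinary genic
    sequence yields five pairs.
    """

    product_size: tuple[int, int] = (100, 250)
    primer_len: tuple[int, int] = (18, 27)
    size_opt: int = 20
    tm_opt: float = 60.0
    tm_range: tuple[float, float] = (55.0, 65.0)
    gc_opt: float = 0.5
    gc_range: tuple[float, float] = (0.25, 0.75)
    max_tm_diff: float = 3.0
    max_homopolymer: int = 5
    max_self_comp_run: int = 8  # hairpin / self-dimer rejection threshold
    w_tm: float = 1.0
    w_size: float = 1.0
    w_gc: float = 1.0  # GC as a fraction, so this contributes at most 0.5
    w_tm_diff: float = 0.5
    conc_nM: float = 50.0  # total strand concentration
    na_mM: float = 50.0
    max_candidates_per_side: int = 400

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PairCandidate:
    left_seq: str
    right_seq: str
    left_start: int  # 0-based on the search sequence
    right_start: int  # 0-based leftmost template base covered by the right primer
    amplicon_len: int
    left_penalty: float
    right_penalty: float
    pair_penalty: float


class PrimerSearchEngine(Protocol):
    name: str

    def design(
        self,
        search_seq: str,
        included_range: tuple[int, int],
        junction: int | None,
        n_pairs: int,
        params: EngineParams,
    ) -> list[PairCandidate]: ...


# ---------------------------------------------------------------------------
# thermodynamics
# ---------------------------------------------------------------------------


def primer_tm(seq: str, params: EngineParams | None = None) -> float:
    """Nearest-neighbor duplex melting temperature of an oligo, in Celsius."""
    params = params or EngineParams()
    seq = seq.upper()
    if set(seq) - set("ACGT"):
        raise ValueError(f"non-ACGT characters in {seq!r}")
    if len(seq) < 2:
        raise ValueError("sequence too short for nearest-neighbor stacking")
    dh, ds = 0.0, 0.0
    for a, b in ((seq[0], None), (seq[-1], None)):
        init = INIT_AT if a in "AT" else INIT_GC
        dh += init[0]
        ds += init[1]
    for i in range(len(seq) - 1):
        h, s = NN_PARAMS[seq[i : i + 2]]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * np.log(params.na_mM / 1000.0)
    conc = params.conc_nM * 1e-9 / 4.0
    return dh * 1000.0 / (ds + R_GAS * np.log(conc)) - 273.15


def primer_gc(seq: str) -> float:
    """GC fraction of an oligo."""
    seq = seq.upper()
    if set(seq) - set("ACGT"):
        raise ValueError(f"non-ACGT characters in {seq!r}")
    return (seq.count("G") + seq.count("C")) / len(seq)


def oligo_penalty(
    seq: str, params: EngineParams | None = None
) -> tuple[float, float, float]:
    """Score one candidate oligo: ``(penalty, tm, gc)``.

    Penalty 0 means the oligo sits exactly at the configured optima.
    """
    params = params or EngineParams()
    if not (15 <= len(seq) <= 36):
        raise ValueError(f"primer length {len(seq)} outside the supported 15-36 nt")
    tm = primer_tm(seq, params)
    gc = primer_gc(seq)
    penalty = (
        params.w_tm * abs(tm - params.tm_opt)
        + params.w_size * abs(len(seq) - params.size_opt)
        + params.w_gc * abs(gc - params.gc_opt)
    )
    return penalty, tm, gc


def has_long_self_complement(seq: str, run: int) -> bool:
    """True when any ``run``-mer of the oligo has its reverse complement
    also present in the oligo — the proxy used for hairpin/self-dimer
    rejection."""
    if len(seq) < run:
        return False
    kmers = {seq[i : i + run] for i in range(len(seq) - run + 1)}
    return any(_revcomp(k) in kmers for k in kmers)


# ---------------------------------------------------------------------------
# built-in engine
# ---------------------------------------------------------------------------


def _candidate_arrays(seq: str, params: EngineParams):
    """Vectorized (start, length) -> (tm, gc, ok) over a whole sequence.

    Duplex thermodynamics are strand-symmetric, so one pass on the plus
    strand serves both left primers (substring itself) and right primers
    (reverse complement of the substring).
    """
    code = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = code.size
    is_g = code == ord("G")
    is_c = code == ord("C")
    is_at = (code == ord("A")) | (code == ord("T"))
    gc_cum = np.concatenate([[0], np.cumsum(is_g | is_c)])
    # dinucleotide stacking sums
    dh_arr = np.zeros(max(n - 1, 0))
    ds_arr = np.zeros(max(n - 1, 0))
    pair_index: dict[tuple[int, int], tuple[float, float]] = {}
    for dinuc, (h, s) in NN_PARAMS.items():
        pair_index[(ord(dinuc[0]), ord(dinuc[1]))] = (h, s)
    for i in range(n - 1):
        h, s = pair_index[(code[i], code[i + 1])]
        dh_arr[i] = h
        ds_arr[i] = s
    dh_cum = np.concatenate([[0], np.cumsum(dh_arr)])
    ds_cum = np.concatenate([[0], np.cumsum(ds_arr)])
    # homopolymer runs longer than allowed: flag every base inside one
    bad = np.zeros(n, dtype=bool)
    run_start = 0
    for i in range(1, n + 1):
        if i == n or code[i] != code[i - 1]:
            if i - run_start > params.max_homopolymer:
                bad[run_start:i] = True
            run_start = i
    bad_cum = np.concatenate([[0], np.cumsum(bad)])

    conc = params.conc_nM * 1e-9 / 4.0
    log_na = np.log(params.na_mM / 1000.0)
    out = {}
    for length in range(params.primer_len[0], params.primer_len[1] + 1):
        if length > n:
            continue
        starts = np.arange(0, n - length + 1)
        ends = starts + length  # half-open
        dh = dh_cum[ends - 1] - dh_cum[starts]
        ds = ds_cum[ends - 1] - ds_cum[starts]
        init_h = np.where(is_at[starts], INIT_AT[0], INIT_GC[0]) + np.where(
            is_at[ends - 1], INIT_AT[0], INIT_GC[0]
        )
        init_s = np.where(is_at[starts], INIT_AT[1], INIT_GC[1]) + np.where(
            is_at[ends - 1], INIT_AT[1], INIT_GC[1]
        )
        ds_total = ds + init_s + 0.368 * (length - 1) * log_na
        tm = (dh + init_h) * 1000.0 / (ds_total + R_GAS * np.log(conc)) - 273.15
        gc = (gc_cum[ends] - gc_cum[starts]) / length
        clean = (bad_cum[ends] - bad_cum[starts]) == 0
        ok = (
            clean
            & (tm >= params.tm_range[0])
            & (tm <= params.tm_range[1])
            & (gc >= params.gc_range[0])
            & (gc <= params.gc_range[1])
        )
        out[length] = (starts, tm, gc, ok)
    return out


@dataclass
class _Oligo:
    start: int
    length: int
    tm: float
    penalty: float

    @property
    def end(self) -> int:  # half-open
        return self.start + self.length


class BuiltinEngine:
    """Self-contained thermodynamic primer search."""

    name = "builtin"

    def design(
        self,
        search_seq: str,
        included_range: tuple[int, int],
        junction: int | None,
        n_pairs: int,
        params: EngineParams | None = None,
    ) -> list[PairCandidate]:
        params = params or EngineParams()
        seq = search_seq.upper()
        if set(seq) - set("ACGT"):
            raise ValueError("search sequence contains non-ACGT characters")
        lo, hi = included_range
        arrays = _candidate_arrays(seq, params)

        def collect(side: str) -> list[_Oligo]:
            found: list[_Oligo] = []
            for length, (starts, tm, gc, ok) in arrays.items():
                within = (starts >= lo) & (starts + length <= hi)
                if junction is not None:
                    if side == "left":
                        within &= starts <= junction - 1
                    else:
                        within &= starts + length >= junction + 1
                sel = np.nonzero(ok & within)[0]
                pen = (
                    params.w_tm * np.abs(tm[sel] - params.tm_opt)
                    + params.w_size * abs(length - params.size_opt)
                    + params.w_gc * np.abs(gc[sel] - params.gc_opt)
                )
                for i, p in zip(sel, pen):
                    found.append(_Oligo(int(starts[i]), length, float(tm[i]), float(p)))
            found.sort(key=lambda o: (o.penalty, o.start, o.length))
            # structure screen on the best candidates only
            kept: list[_Oligo] = []
            for o in found:
                sub = seq[o.start : o.end]
                primer = sub if side == "left" else _revcomp(sub)
                if has_long_self_complement(primer, params.max_self_comp_run):
                    continue
                kept.append(o)
                if len(kept) >= params.max_candidates_per_side:
                    break
            return kept

        lefts = collect("left")
        rights = collect("right")
        if not lefts or not rights:
            return []

        min_prod, max_prod = params.product_size
        lstart = np.array([o.start for o in lefts])
        lend = np.array([o.end for o in lefts])
        lpen = np.array([o.penalty for o in lefts])
        ltm = np.array([o.tm for o in lefts])
        rstart = np.array([o.start for o in rights])
        rend = np.array([o.end for o in rights])
        rpen = np.array([o.penalty for o in rights])
        rtm = np.array([o.tm for o in rights])

        amplicon = rend[None, :] - lstart[:, None]
        tm_diff = np.abs(ltm[:, None] - rtm[None, :])
        valid = (
            (amplicon >= min_prod)
            & (amplicon <= max_prod)
            & (rstart[None, :] >= lend[:, None])
            & (tm_diff <= params.max_tm_diff)
        )
        if junction is not None:
            valid &= (lstart[:, None] <= junction - 1) & (rend[None, :] >= junction + 1)
        pair_pen = lpen[:, None] + rpen[None, :] + params.w_tm_diff * tm_diff
        pair_pen[~valid] = np.inf
        flat = np.argsort(pair_pen, axis=None, kind="stable")

        results: list[PairCandidate] = []
        seen: set[tuple[int, int]] = set()
        for idx in flat:
            li, ri = divmod(int(idx), len(rights))
            if not np.isfinite(pair_pen[li, ri]):
                break
            l, r = lefts[li], rights[ri]
            key = (l.start, r.start)
            if key in seen:
                continue
            seen.add(key)
            results.append(
                PairCandidate(
                    left_seq=seq[l.start : l.end],
                    right_seq=_revcomp(seq[r.start : r.end]),
                    left_start=l.start,
                    right_start=r.start,
                    amplicon_len=int(r.end - l.start),
                    left_penalty=round(l.penalty, 6),
                    right_penalty=round(r.penalty, 6),
                    pair_penalty=round(float(pair_pen[li, ri]), 6),
                )
            )
            if len(results) >= n_pairs:
                break
        return results


class Primer3Engine:
    """Binding to the external Primer3 library (optional dependency)."""

    name = "primer3"

    def __init__(self) -> None:
        try:
            import primer3  # noqa: F401
        except ImportError as exc:  # pragma: no cover - depends on extras
            raise ImportError(
                "the external Primer3 engine needs the primer3-py package "
                "(pip install refprime[primer3]); the builtin engine has no "
                "such requirement"
            ) from exc
        self._primer3 = primer3

    def design(
        self,
        search_seq: str,
        included_range: tuple[int, int],
        junction: int | None,
        n_pairs: int,
        params: EngineParams | None = None,
    ) -> list[PairCandidate]:  # pragma: no cover - depends on extras
        params = params or EngineParams()
        lo, hi = included_range
        seq_args = {
            "SEQUENCE_ID": "region",
            "SEQUENCE_TEMPLATE": search_seq,
            "SEQUENCE_INCLUDED_REGION": [lo, hi - lo],
        }
        if junction is not None:
            seq_args["SEQUENCE_TARGET"] = [junction - 1, 2]
        global_args = {
            "PRIMER_NUM_RETURN": n_pairs,
            "PRIMER_PRODUCT_SIZE_RANGE": [list(params.product_size)],
            "PRIMER_MIN_SIZE": params.primer_len[0],
            "PRIMER_MAX_SIZE": params.primer_len[1],
            "PRIMER_OPT_SIZE": params.size_opt,
            "PRIMER_OPT_TM": params.tm_opt,
            "PRIMER_MIN_TM": params.tm_range[0],
            "PRIMER_MAX_TM": params.tm_range[1],
            "PRIMER_OPT_GC_PERCENT": params.gc_opt * 100,
            "PRIMER_MIN_GC": params.gc_range[0] * 100,
            "PRIMER_MAX_GC": params.gc_range[1] * 100,
            "PRIMER_PAIR_MAX_DIFF_TM": params.max_tm_diff,
        }
        res = self._primer3.bindings.design_primers(seq_args, global_args)
        out = []
        for i in range(res.get("PRIMER_PAIR_NUM_RETURNED", 0)):
            ls, ll = res[f"PRIMER_LEFT_{i}"]
            rs, rl = res[f"PRIMER_RIGHT_{i}"]  # rs is the 3' end (5' on minus)
            out.append(
                PairCandidate(
                    left_seq=res[f"PRIMER_LEFT_{i}_SEQUENCE"],
                    right_seq=res[f"PRIMER_RIGHT_{i}_SEQUENCE"],
                    left_start=ls,
                    right_start=rs - rl + 1,
                    amplicon_len=rs - ls + 1,
                    left_penalty=res[f"PRIMER_LEFT_{i}_PENALTY"],
                    right_penalty=res[f"PRIMER_RIGHT_{i}_PENALTY"],
                    pair_penalty=res[f"PRIMER_PAIR_{i}_PENALTY"],
                )
            )
        return out


def get_engine(name: str) -> PrimerSearchEngine:
    if name == "builtin":
        return BuiltinEngine()
    if name == "primer3":
        return Primer3Engine()
    raise ValueError(f"unknown engine {name!r}; choose 'builtin' or 'primer3'")
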