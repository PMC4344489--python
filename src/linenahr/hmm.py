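"""Crossover localization inside a LINE-LINE homology from junction reads.

A NAHR junction amplicon starts as proximal-LINE sequence and ends as
distal-LINE sequence; the crossover lies between the last read base
supporting the proximal copy and the first supporting the distal copy.
Each aligned read base at a *cis-morphism* (a column where the two copies
disagree) votes L (left/proximal allele), R (right/distal allele) or N
(uninformative); all other columns are N.  The vote string S ... E is
modelled by a two-state HMM: state S1 emits L with probability alpha
(given an informative emission), state S2 emits R with probability beta,
either state emits N with probability rho, and the chain may switch
S1 -> S2 once with per-symbol hazard gamma.  The posterior of the switch
position localizes the crossover between flanking cis-morphisms.

Base-call confidence enters through the emission matrix: an observed L
with PHRED-derived weight w = 1 - 10**(-Q/10) is scored with the affine
combination w * b(L) + (1 - w) * b(R) (and symmetrically for R), so a
low-quality vote pulls the likelihood toward indifference.

Training is expectation-maximization with Beta-prior MAP updates
(Baum-Welch with pseudo-counts); the forward-backward recursions use
per-position scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .synthetic import revcomp

# ---------------------------------------------------------------------------
# consensus and cis-morphism map
# ---------------------------------------------------------------------------

COL_IDENTICAL = 0
COL_CIS = 1
COL_INDEL = 2


@dataclass
class CisMorphismMap:
    """Columns of the pairwise alignment of the two LINE copies.

    ``consensus`` carries one base per column (at substitution columns the
    proximal allele; at indel columns the base of whichever copy has one).
    ``informative`` lists (column, left allele, right allele) for
    substitution columns; indel columns are excluded from informativeness
    and encode as N.
    """

    consensus: str
    flags: np.ndarray  # per column: COL_IDENTICAL | COL_CIS | COL_INDEL
    informative: list[tuple[int, str, str]]
    offset_left: np.ndarray  # per column: offset into the left copy
    offset_right: np.ndarray  # per column: offset into the right copy

    @property
    def informative_columns(self) -> np.ndarray:
        return np.array([c for c, _, _ in self.informative], dtype=int)


def build_consensus(seq_left: str, seq_right: str) -> CisMorphismMap:
    """Globally align the two copies and map their cis-morphisms.

    Scoring: match +1, mismatch -1, gap open -5, gap extend -1.
    """
    if not seq_left or not seq_right:
        raise ValueError("both sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    aln = aligner.align(seq_left, seq_right)[0]
    top, bot = str(aln[0]), str(aln[1])
    cons = []
    flags = np.empty(len(top), dtype=int)
    informative: list[tuple[int, str, str]] = []
    off_l = np.empty(len(top), dtype=int)
    off_r = np.empty(len(top), dtype=int)
    i_l = i_r = 0
    for i, (a, b) in enumerate(zip(top, bot)):
        off_l[i], off_r[i] = i_l, i_r
        if a == "-" or b == "-":
            flags[i] = COL_INDEL
            cons.append(a if b == "-" else b)
        elif a == b:
            flags[i] = COL_IDENTICAL
            cons.append(a)
        else:
            flags[i] = COL_CIS
            informative.append((i, a, b))
            cons.append(a)
        i_l += a != "-"
        i_r += b != "-"
    return CisMorphismMap(
        consensus="".join(cons), flags=flags, informative=informative,
        offset_left=off_l, offset_right=off_r,
    )


# ---------------------------------------------------------------------------
# semi-global read alignment
# ---------------------------------------------------------------------------

@dataclass
class ReadAlignment:
    score: float
    orientation: str  # forward | reverse
    read: str  # in consensus orientation
    columns: np.ndarray  # consensus column per read base; -1 for insertions
    identity: float  # matches / aligned read bases


_GAP = 2  # linear gap penalty (positive magnitude)
_MATCH = 1
_MISMATCH = -1


def _semiglobal_matrix(read: str, ref: str) -> np.ndarray:
    """Fill the semi-global DP matrix (free ref end-gaps), vectorized by row.

    Linear gap costs make the in-row dependency a running maximum, so each
    row is two numpy scans instead of a python loop over columns.
    """
    m, n = len(read), len(ref)
    ref_arr = np.frombuffer(ref.encode(), dtype="S1")
    h = np.empty((m + 1, n + 1), dtype=np.int32)
    h[0, :] = 0
    j_idx = np.arange(n + 1, dtype=np.int32) * _GAP
    for i in range(1, m + 1):
        sub = np.where(ref_arr == read[i - 1].encode(), _MATCH, _MISMATCH).astype(np.int32)
        v = np.maximum(h[i - 1, :-1] + sub, h[i - 1, 1:] - _GAP)
        row = np.empty(n + 1, dtype=np.int32)
        row[0] = h[i - 1, 0] - _GAP
        # h[i, j] = max(v[j], h[i, j-1] - GAP)  ->  prefix max of (x + GAP*j)
        stacked = np.maximum.accumulate(np.concatenate(([row[0] + j_idx[0]], v + j_idx[1:])))
        row = stacked - j_idx
        h[i] = row
    return h


def semiglobal_score(read: str, ref: str) -> int:
    """Optimal semi-global score (read inside ref, ref end-gaps free)."""
    if not read:
        raise ValueError("empty read")
    if len(read) > len(ref):
        raise ValueError("read longer than reference")
    return int(_semiglobal_matrix(read, ref)[-1].max())


def _traceback(h: np.ndarray, read: str, ref: str) -> tuple[np.ndarray, int]:
    m, n = len(read), len(ref)
    j = int(np.argmax(h[m]))
    i = m
    cols = np.full(m, -1, dtype=int)
    matches = 0
    while i > 0:
        if j > 0:
            diag = h[i - 1, j - 1] + (_MATCH if read[i - 1] == ref[j - 1] else _MISMATCH)
            if h[i, j] == diag:
                cols[i - 1] = j - 1
                matches += int(read[i - 1] == ref[j - 1])
                i, j = i - 1, j - 1
                continue
        if h[i, j] == h[i - 1, j] - _GAP:
            i -= 1  # read base inserted relative to consensus
            continue
        j -= 1  # consensus base skipped (read deletion)
    return cols, matches


def align_read_semiglobal(read: str, consensus: str) -> ReadAlignment:
    """Place a read inside the consensus; both orientations tried.

    Returns the better-scoring orientation with the per-base consensus
    column mapping (-1 for read bases inserted relative to the consensus).
    """
    if not read:
        raise ValueError("empty read")
    if len(read) > len(consensus):
        raise ValueError("read longer than consensus")
    best = None
    for orientation, seq in (("forward", read), ("reverse", revcomp(read))):
        h = _semiglobal_matrix(seq, consensus)
        score = int(h[-1].max())
        if best is None or score > best[0]:
            best = (score, orientation, seq, h)
    score, orientation, seq, h = best
    cols, matches = _traceback(h, seq, consensus)
    return ReadAlignment(
        score=float(score),
        orientation=orientation,
        read=seq,
        columns=cols,
        identity=100.0 * matches / len(seq),
    )


# ---------------------------------------------------------------------------
# observation encoding
# ---------------------------------------------------------------------------

@dataclass
class ObsSequence:
    """S ... E vote string with per-symbol confidence and column mapping."""

    symbols: str  # 'S' + body over {L,R,N} + 'E'
    weights: np.ndarray  # per body symbol; meaningful for L/R only
    columns: np.ndarray  # consensus column per body symbol

    def __post_init__(self) -> None:
        if not (self.symbols.startswith("S") and self.symbols.endswith("E")):
            raise ValueError("observation must start with S and end with E")
        body = self.symbols[1:-1]
        if len(body) != len(self.weights) or len(body) != len(self.columns):
            raise ValueError("weights/columns must match the body length")
        if any(c not in "LRN" for c in body):
            raise ValueError("body symbols must be L, R or N")

    @property
    def body(self) -> str:
        return self.symbols[1:-1]


def encode_observations(
    alignment: ReadAlignment,
    cis_map: CisMorphismMap,
    quals: list[int] | None = None,
) -> ObsSequence:
    """Encode one aligned read as an S/N/L/R/E vote string.

    Covered informative columns vote L or R by allele (N on mismatch to
    both or on a read gap); every other covered column is N.  L/R votes
    carry w = 1 - 10**(-Q/10) from the underlying base's PHRED quality.
    """
    allele = {c: (l, r) for c, l, r in cis_map.informative}
    base_at: dict[int, tuple[str, int]] = {}
    for i, col in enumerate(alignment.columns):
        if col >= 0:
            q = quals[i] if quals is not None else 40
            base_at[int(col)] = (alignment.read[i], q)
    covered = [int(c) for c in alignment.columns if c >= 0]
    if not covered:
        raise ValueError("read alignment covers no consensus columns")
    lo, hi = min(covered), max(covered)
    symbols = ["S"]
    weights: list[float] = []
    columns: list[int] = []
    for col in range(lo, hi + 1):
        if col in allele and col in base_at:
            base, q = base_at[col]
            left, right = allele[col]
            if base == left:
                sym = "L"
            elif base == right:
                sym = "R"
            else:
                sym = "N"
            w = 1.0 - 10 ** (-q / 10.0)
        else:
            sym, w = "N", 1.0
        symbols.append(sym)
        weights.append(w)
        columns.append(col)
    symbols.append("E")
    return ObsSequence(
        symbols="".join(symbols),
        weights=np.array(weights),
        columns=np.array(columns, dtype=int),
    )


# ---------------------------------------------------------------------------
# model parameters
# ---------------------------------------------------------------------------

@dataclass
class HMMParams:
    """Emission/transition parameters with their Beta priors.

    alpha: P(L | informative emission, S1); beta: P(R | informative, S2);
    gamma: per-symbol S1 -> S2 switch hazard; rho: P(N) in either state.
    """

    alpha: float = 0.95
    beta: float = 0.95
    gamma: float = 0.01
    rho: float = 0.5
    priors: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "alpha": (20.0, 1.0),
            "beta": (20.0, 1.0),
            "gamma": (1.0, 20.0),
            "rho": (2.0, 2.0),
        }
    )
    trained: bool = False

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "rho"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} = {v} outside (0, 1)")

    def emission_rows(self) -> dict[str, np.ndarray]:
        """Per-symbol emission vectors (S1, S2)."""
        a, b, r = self.alpha, self.beta, self.rho
        return {
            "L": np.array([(1 - r) * a, (1 - r) * (1 - b)]),
            "R": np.array([(1 - r) * (1 - a), (1 - r) * b]),
            "N": np.array([r, r]),
        }


def _emission_matrix(obs: ObsSequence, params: HMMParams) -> np.ndarray:
    """(T, 2) likelihoods with the PHRED affine combination applied to L/R."""
    rows = params.emission_rows()
    t_len = len(obs.body)
    e = np.empty((t_len, 2))
    for t, sym in enumerate(obs.body):
        if sym == "N":
            e[t] = rows["N"]
        else:
            w = obs.weights[t]
            other = "R" if sym == "L" else "L"
            e[t] = w * rows[sym] + (1.0 - w) * rows[other]
    return e


# ---------------------------------------------------------------------------
# forward-backward
# ---------------------------------------------------------------------------

@dataclass
class _FB:
    f: np.ndarray  # scaled forward, (T, 2)
    b: np.ndarray  # scaled backward, (T, 2)
    scale: np.ndarray  # per-position scaling factors
    loglik: float
    e: np.ndarray  # emission matrix used


def _forward_backward(obs: ObsSequence, params: HMMParams, force_switch: bool) -> _FB:
    e = _emission_matrix(obs, params)
    t_len = e.shape[0]
    g = params.gamma
    pi = np.array([1.0 - g, g])
    a_mat = np.array([[1.0 - g, g], [0.0, 1.0]])
    u = np.array([g, 1.0]) if force_switch else np.array([1.0, 1.0])

    f = np.empty((t_len, 2))
    scale = np.empty(t_len)
    f[0] = pi * e[0]
    scale[0] = f[0].sum()
    if scale[0] <= 0:
        raise ValueError("zero forward likelihood at position 0")
    f[0] /= scale[0]
    for t in range(1, t_len):
        f[t] = (f[t - 1] @ a_mat) * e[t]
        scale[t] = f[t].sum()
        if scale[t] <= 0 or not np.isfinite(scale[t]):
            raise ValueError(f"non-finite forward likelihood at position {t}")
        f[t] /= scale[t]
    tail = float(f[-1] @ u)
    if tail <= 0:
        raise ValueError("observation has zero likelihood under the model")
    loglik = float(np.log(scale).sum() + np.log(tail))

    b = np.empty((t_len, 2))
    b[-1] = u / scale[-1]
    for t in range(t_len - 2, -1, -1):
        b[t] = (a_mat * e[t + 1] * b[t + 1]).sum(axis=1) / scale[t]
    return _FB(f=f, b=b, scale=scale, loglik=loglik, e=e)


def _posteriors(
    fb: _FB, gamma: float, force_switch: bool
) -> tuple[np.ndarray, np.ndarray]:
    """State marginals P(state_t | obs) and switch-point posteriors.

    xi[t] = P(switch between body symbols t and t+1 | obs) for t = 0..T
    (t = 0: before the first symbol; t = T: just before E, a real path
    only when the switch is forced).  With scaled forward/backward
    variables, f_hat(t-1) * gamma * e(t) * b_hat(t) equals the unscaled
    ratio up to the terminal weight `tail`, which both quantities divide
    out.
    """
    t_len = fb.e.shape[0]
    u = np.array([gamma, 1.0]) if force_switch else np.array([1.0, 1.0])
    tail = float(fb.f[-1] @ u)
    post = fb.f * fb.b * fb.scale[:, None] / tail
    xi = np.zeros(t_len + 1)
    xi[0] = gamma * fb.e[0, 1] * fb.b[0, 1] / tail
    xi[1:t_len] = fb.f[:-1, 0] * gamma * fb.e[1:, 1] * fb.b[1:, 1] / tail
    if force_switch:
        xi[t_len] = fb.f[-1, 0] * gamma / tail
    return post, xi


def switch_posterior(
    obs: ObsSequence, params: HMMParams, force_switch: bool = True
) -> tuple[np.ndarray, float]:
    """Posterior of the S1 -> S2 switch at each of the T+1 possible points.

    Point t means the switch happened between body symbols t and t+1
    (t = 0: before the first symbol; t = T: after the last, just before E).
    With ``force_switch`` the vector sums to 1 (up to rounding); otherwise
    it is conditioned on a switch having occurred and the second return
    value is the total switch probability.
    """
    fb = _forward_backward(obs, params, force_switch)
    _, xi = _posteriors(fb, params.gamma, force_switch)
    p_switch = float(xi.sum())
    if force_switch:
        return xi / p_switch, 1.0
    if p_switch <= 0:
        return xi, 0.0
    return xi / p_switch, p_switch


# ---------------------------------------------------------------------------
# Baum-Welch with Beta-MAP updates
# ---------------------------------------------------------------------------

def _log_prior(params: HMMParams) -> float:
    lp = 0.0
    for name, (a, b) in params.priors.items():
        x = getattr(params, name)
        lp += (a - 1.0) * np.log(x) + (b - 1.0) * np.log(1.0 - x)
    return float(lp)


def baum_welch(
    obs_set: list[ObsSequence],
    init: HMMParams | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    force_switch: bool = False,
) -> tuple[HMMParams, list[float]]:
    """MAP expectation-maximization for (alpha, beta, gamma, rho).

    Expected counts from forward-backward plus Beta pseudo-counts; stops
    when the penalized log-likelihood improves by less than ``tol``.  The
    returned trace (penalized log-likelihood per iteration) is
    non-decreasing up to numerical noise.
    """
    if not obs_set:
        raise ValueError("baum_welch needs at least one observation sequence")
    params = init or HMMParams()
    priors = params.priors
    trace: list[float] = []
    for _ in range(max_iter):
        rows = params.emission_rows()
        n_switch = 0.0
        n_s1_decisions = 0.0
        n1_l = n1_r = n2_l = n2_r = 0.0
        n_n = 0.0
        n_total = 0.0
        loglik = 0.0
        for k, obs in enumerate(obs_set):
            try:
                fb = _forward_backward(obs, params, force_switch)
            except ValueError as exc:
                raise ValueError(f"sequence {k}: {exc}") from exc
            loglik += fb.loglik
            post, xi = _posteriors(fb, params.gamma, force_switch)
            n_switch += float(xi.sum())
            # hazard decisions taken while in S1: the initial one, one
            # before each later symbol (only if still in S1), and the
            # terminal one when a switch is forced
            n_s1_decisions += 1.0 + float(post[:-1, 0].sum())
            if force_switch:
                n_s1_decisions += float(post[-1, 0])
            for t, sym in enumerate(obs.body):
                n_total += 1.0
                if sym == "N":
                    n_n += 1.0
                    continue
                w = obs.weights[t]
                other = "R" if sym == "L" else "L"
                for s in (0, 1):
                    num_obs = w * rows[sym][s]
                    num_other = (1.0 - w) * rows[other][s]
                    denom = num_obs + num_other
                    if denom <= 0:
                        continue
                    p_true_obs = num_obs / denom
                    p_l = p_true_obs if sym == "L" else 1.0 - p_true_obs
                    if s == 0:
                        n1_l += post[t, 0] * p_l
                        n1_r += post[t, 0] * (1.0 - p_l)
                    else:
                        n2_l += post[t, 1] * p_l
                        n2_r += post[t, 1] * (1.0 - p_l)
        penalized = loglik + _log_prior(params)
        trace.append(penalized)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            break

        def map_est(succ: float, fail: float, prior: tuple[float, float]) -> float:
            a, b = prior
            val = (succ + a - 1.0) / (succ + fail + a + b - 2.0)
            return float(np.clip(val, 1e-6, 1.0 - 1e-6))

        params = HMMParams(
            alpha=map_est(n1_l, n1_r, priors["alpha"]),
            beta=map_est(n2_r, n2_l, priors["beta"]),
            gamma=map_est(n_switch, n_s1_decisions - n_switch, priors["gamma"]),
            rho=map_est(n_n, n_total - n_n, priors["rho"]),
            priors=priors,
            trained=True,
        )
    params.trained = True
    return params, trace


# ---------------------------------------------------------------------------
# breakpoint calls
# ---------------------------------------------------------------------------

@dataclass
class BreakpointCall:
    """Posterior localization of the crossover on consensus coordinates.

    ``intervals`` are the gaps between adjacent informative columns that
    could contain the switch (plus the two open flanks); ``masses`` their
    posterior probabilities.  The MAP interval is reported between the
    flanking discordant cis-morphisms; ties break to the leftmost.
    """

    intervals: list[tuple[int, int]]
    masses: np.ndarray
    map_interval: tuple[int, int]
    map_mass: float
    p_switch: float
    n_reads: int = 1

    @property
    def map_length(self) -> int:
        return self.map_interval[1] - self.map_interval[0]


def _interval_posterior(
    obs: ObsSequence,
    xi: np.ndarray,
    informative_cols: np.ndarray,
    consensus_len: int,
) -> dict[tuple[int, int], float]:
    """Aggregate switch-point posterior into inter-cis-morphism intervals."""
    bounds = np.concatenate(([-1], informative_cols.astype(int), [consensus_len]))
    cols = obs.columns
    t_len = len(cols)
    # switch point t lies between consensus columns left_col[t], right_col[t]
    left_col = np.concatenate(([-1], cols))
    right_col = np.concatenate((cols, [consensus_len]))
    lo = bounds[np.searchsorted(bounds, left_col, side="right") - 1]
    hi = bounds[np.searchsorted(bounds, right_col, side="left")]
    masses: dict[tuple[int, int], float] = {}
    for t in range(t_len + 1):
        if xi[t] <= 0:
            continue
        key = (int(lo[t]), int(hi[t]))
        masses[key] = masses.get(key, 0.0) + float(xi[t])
    return masses


def posterior_breakpoint(
    obs: ObsSequence,
    params: HMMParams,
    cis_map: CisMorphismMap,
    force_switch: bool = True,
) -> BreakpointCall:
    """Quality-weighted forward-backward switch posterior for one read."""
    xi, p_switch = switch_posterior(obs, params, force_switch)
    masses = _interval_posterior(
        obs, xi, cis_map.informative_columns, len(cis_map.consensus)
    )
    intervals = sorted(masses)
    vec = np.array([masses[k] for k in intervals])
    best = int(np.argmax(vec))  # argmax takes the first (leftmost) on ties
    return BreakpointCall(
        intervals=intervals,
        masses=vec,
        map_interval=intervals[best],
        map_mass=float(vec[best]),
        p_switch=p_switch,
    )


def encode_case_reads(
    reads: list[tuple[str, str, list[int]]],
    seq_left: str,
    seq_right: str,
    min_read_identity: float = 80.0,
) -> tuple[CisMorphismMap, list[ObsSequence]]:
    """Align and encode one case's reads against the pair consensus.

    Reads aligning below ``min_read_identity`` percent are dropped with a
    warning; raises when none remain.
    """
    import logging

    log = logging.getLogger(__name__)
    cis = build_consensus(seq_left, seq_right)
    obs_list: list[ObsSequence] = []
    for name, seq, quals in reads:
        aln = align_read_semiglobal(seq, cis.consensus)
        if aln.identity < min_read_identity:
            log.warning("read %s dropped: identity %.1f%% to consensus", name, aln.identity)
            continue
        quals_used = quals if aln.orientation == "forward" else quals[::-1]
        obs_list.append(encode_observations(aln, cis, quals_used))
    if not obs_list:
        raise ValueError("no reads aligned to the consensus at sufficient identity")
    return cis, obs_list


def pool_breakpoint(
    obs_list: list[ObsSequence],
    cis: CisMorphismMap,
    params: HMMParams,
    force_switch: bool = True,
    n_reads: int | None = None,
) -> BreakpointCall:
    """Combine per-read switch posteriors by product over shared intervals."""
    per_read: list[dict[tuple[int, int], float]] = []
    for obs in obs_list:
        xi, _ = switch_posterior(obs, params, force_switch)
        per_read.append(
            _interval_posterior(obs, xi, cis.informative_columns, len(cis.consensus))
        )
    floor = 1e-12
    keys = sorted(set().union(*per_read))
    intervals = keys
    logs = np.array(
        [
            sum(np.log(max(m.get(k, 0.0), floor)) for m in per_read)
            for k in keys
        ]
    )
    logs -= logs.max()
    vec = np.exp(logs)
    vec /= vec.sum()
    best = int(np.argmax(vec))
    return BreakpointCall(
        intervals=intervals,
        masses=vec,
        map_interval=intervals[best],
        map_mass=float(vec[best]),
        p_switch=1.0,
        n_reads=n_reads if n_reads is not None else len(obs_list),
    )


def call_case(
    reads: list[tuple[str, str, list[int]]],
    seq_left: str,
    seq_right: str,
    params: HMMParams | None = None,
    min_read_identity: float = 80.0,
    force_switch: bool = True,
) -> BreakpointCall:
    """Pool junction reads of one case into a single breakpoint call.

    With no trained parameters supplied the model is trained on this
    case's reads alone; when many cases share a model, train once on all
    their observations (:func:`encode_case_reads` + :func:`baum_welch`)
    and pass the result — small per-case read sets leave the emission
    parameters close to their priors, which blunts localization.
    """
    cis, obs_list = encode_case_reads(reads, seq_left, seq_right, min_read_identity)
    if params is None:
        params, _ = baum_welch(obs_list, force_switch=force_switch)
    return pool_breakpoint(obs_list, cis, params, force_switch)


def cluster_calls(
    calls: list[BreakpointCall], max_distance: int = 500
) -> list[int]:
    """Single-linkage clustering of MAP-interval midpoints across cases.

    Calls whose midpoints lie within ``max_distance`` bp end up in the same
    cluster; returns a cluster label per call.  Distinct labels for
    distinct NAHR loci support the hotspot observation.
    """
    mids = [(lo + hi) / 2 for lo, hi in (c.map_interval for c in calls)]
    order = sorted(range(len(calls)), key=lambda i: mids[i])
    labels = [0] * len(calls)
    cluster = 0
    prev = None
    for idx in order:
        if prev is not None and mids[idx] - prev > max_distance:
            cluster += 1
        labels[idx] = cluster
        prev = mids[idx]
    return labels


# ---------------------------------------------------------------------------
# observation simulator (for calibration and tests)
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCase:
    seq_left: str
    seq_right: str
    reads: list[tuple[str, str, list[int]]]
    crossover_column: int  # true switch position on the consensus
    cis: CisMorphismMap


def simulate_junction_case(
    seed: int,
    homology_length: int = 2500,
    divergence: float = 0.01,
    indel_rate: float = 0.0002,
    n_reads: int = 2,
    read_length: int = 500,
    quality: int = 40,
    margin: int = 60,
) -> SimulatedCase:
    """One synthetic NAHR case: a diverged pair, a hybrid, junction reads.

    ``divergence`` is the per-copy substitution rate from the common
    ancestor, so the pairwise cis-morphism density is ~2x that (a 1
    percent rate gives roughly one informative site per 50 bp).  The
    crossover column is drawn uniformly from identical (non-cis,
    non-indel) consensus columns away from the homology ends, matching
    the biology: strand exchange requires locally perfect homology.
    """
    from .synthetic import mutate, random_sequence, simulate_junction_reads

    rng = np.random.default_rng(seed)
    anc = random_sequence(rng, homology_length)
    seq_left = mutate(rng, anc, divergence, indel_rate)
    seq_right = mutate(rng, anc, divergence, indel_rate)
    cis = build_consensus(seq_left, seq_right)
    n_cols = len(cis.consensus)
    lo = read_length // 2 + margin
    hi = n_cols - read_length // 2 - margin
    candidates = np.nonzero(cis.flags[lo:hi] == COL_IDENTICAL)[0] + lo
    if candidates.size == 0:
        raise ValueError("homology too short for the requested read length")
    c = int(candidates[rng.integers(candidates.size)])
    pos_l = int(cis.offset_left[c])
    pos_r = int(cis.offset_right[c])
    hybrid = seq_left[:pos_l] + seq_right[pos_r:]
    reads, _ = simulate_junction_reads(
        hybrid, junction=pos_l, n_reads=n_reads, read_length=read_length,
        quality=quality, seed=int(rng.integers(2**31)), margin=margin,
    )
    return SimulatedCase(
        seq_left=seq_left, seq_right=seq_right, reads=reads,
        crossover_column=c, cis=cis,
    )


def sample_observations(
    params: HMMParams,
    n_seqs: int,
    length: int,
    seed: int,
    weight: float = 1.0,
) -> list[ObsSequence]:
    """Draw vote strings from the model itself (no forced switch)."""
    rng = np.random.default_rng(seed)
    rows = params.emission_rows()
    out = []
    for _ in range(n_seqs):
        state = 0
        symbols = []
        for _t in range(length):
            if state == 0 and rng.random() < params.gamma:
                state = 1
            probs = np.array([rows[s][state] for s in ("L", "R", "N")])
            sym = ("L", "R", "N")[rng.choice(3, p=probs / probs.sum())]
            symbols.append(sym)
        out.append(
            ObsSequence(
                symbols="S" + "".join(symbols) + "E",
                weights=np.full(length, weight),
                columns=np.arange(length),
            )
        )
    return out
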