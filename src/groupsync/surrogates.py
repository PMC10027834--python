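"""Surrogate-data baselines: segment shuffling and variable swapping.

Both methods preserve each channel's marginal distribution exactly while
destroying the temporal relationships *between* channels, yielding a
chance-level reference for any synchrony metric.  Variable swapping also
preserves each channel's full autocorrelation structure and is the
preferred baseline in the experiment drivers: segment shuffling breaks
within-channel continuity at the cut points, which can move metrics even
when no synchrony is present.
"""

from __future__ import annotations

import numpy as np

from .core import (
    MultivariateTimeSeries,
    ParameterError,
    SampleCollection,
    ValidationError,
    as_array,
    validate_collection,
)

__all__ = ["shuffle_segments", "swap_variables"]


def shuffle_segments(
    series,
    segment_length: int,
    rng: np.random.Generator,
) -> MultivariateTimeSeries:
    """Cut each variable into consecutive segments and permute them independently.

    The trailing partial segment (when segment_length does not divide the
    series length) is kept and shuffled as its own segment.  Each variable's
    multiset of values is preserved exactly.
    """
    values = as_array(series).copy()
    n_var, n_t = values.shape
    if segment_length < 1 or segment_length > n_t:
        raise ParameterError(
            f"segment_length must be in [1, {n_t}], got {segment_length}"
        )
    boundaries = list(range(0, n_t, segment_length)) + [n_t]
    out = np.empty_like(values)
    for k in range(n_var):
        segments = [values[k, a:b] for a, b in zip(boundaries[:-1], boundaries[1:])]
        order = rng.permutation(len(segments))
        out[k] = np.concatenate([segments[i] for i in order])
    interval = series.sample_interval if isinstance(series, MultivariateTimeSeries) else 1.0
    return MultivariateTimeSeries(out, sample_interval=interval)


def _constrained_assignment(
    n_members: int, n_vars: int, rng: np.random.Generator, max_restarts: int = 200
) -> np.ndarray:
    """Draw an (n_members, n_vars) matrix of source members such that every
    column is a permutation of the members (each member donates one channel
    per slot) and no row repeats a member.

    Built column by column as random bipartite matchings: rows are visited in
    random order and each picks a member not yet used in the column and not
    already present in that row; dead ends trigger a retry.
    """
    for _ in range(max_restarts):
        sources = np.full((n_members, n_vars), -1, dtype=int)
        ok = True
        for j in range(n_vars):
            for _ in range(50):  # retries for this column
                column = np.full(n_members, -1, dtype=int)
                used = set()
                for i in rng.permutation(n_members):
                    allowed = [
                        m for m in range(n_members)
                        if m not in used and m not in sources[i, :j]
                    ]
                    if not allowed:
                        break
                    pick = allowed[rng.integers(len(allowed))]
                    column[i] = pick
                    used.add(pick)
                if -1 not in column:
                    sources[:, j] = column
                    break
            else:
                ok = False
                break
        if ok:
            return sources
    raise ValidationError(
        "could not find a same-member-free assignment; "
        "use forbid_same_member=False"
    )  # pragma: no cover - reachable only for tiny pathological shapes


def swap_variables(
    collection: SampleCollection | np.ndarray,
    rng: np.random.Generator,
    forbid_same_member: bool = True,
) -> SampleCollection:
    """Reassign the pooled channels of a sample into new recordings.

    All members must share both variable count and time length.  Every
    original channel appears exactly once in the output and its internal
    values (hence its autocorrelation) are untouched; only the grouping into
    recordings changes.  With ``forbid_same_member`` (default) no surrogate
    recording receives two channels from the same original recording, so no
    genuine within-recording synchrony can leak into the baseline; this
    requires n_variables <= n_members.
    """
    if isinstance(collection, SampleCollection):
        coll = collection
    else:
        arr = np.asarray(collection, dtype=float)
        if arr.ndim != 3:
            raise ValidationError("expected (n_members, n_variables, n_timesteps) array")
        coll = validate_collection([MultivariateTimeSeries(a) for a in arr])
    stacked = coll.stack()  # raises if lengths differ
    n_members, n_vars, n_t = stacked.shape
    if forbid_same_member:
        if n_vars > n_members:
            raise ValidationError(
                f"forbid_same_member needs n_variables ({n_vars}) <= "
                f"n_members ({n_members})"
            )
        sources = _constrained_assignment(n_members, n_vars, rng)
        # each member m is drawn exactly n_vars times; hand out its channels
        # in a random order so every original channel is used once
        var_order = [rng.permutation(n_vars) for _ in range(n_members)]
        cursor = np.zeros(n_members, dtype=int)
        out = np.empty_like(stacked)
        for i in range(n_members):
            for j in range(n_vars):
                m = sources[i, j]
                v = var_order[m][cursor[m]]
                cursor[m] += 1
                out[i, j] = stacked[m, v]
    else:
        flat = stacked.reshape(n_members * n_vars, n_t)
        out = flat[rng.permutation(n_members * n_vars)].reshape(stacked.shape)
    interval = coll.series[0].sample_interval
    return validate_collection(
        [MultivariateTimeSeries(a, sample_interval=interval) for a in out]
    )
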