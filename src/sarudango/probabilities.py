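"""Join/leave probability rules.

These two formulas are the behavioural heart of the model: every emergent
huddling pattern follows from agents comparing a uniform draw against them.

* ``p_join = (n_ci / n_cmax) * (1 / T) * (1 / J)`` — joining is more likely
  the larger the candidate cluster, less likely the warmer it is and the more
  selective the agent (large J).
* ``p_leave = ((n_cmax - n_ci) / n_cmax) * (1 / L)`` — leaving is less likely
  the larger the agent's own cluster and the more committed the agent
  (large L); a cluster containing the whole group is never left.

The expressions below are kept textually identical to the compiled engine in
``_engine.py`` so that both paths produce bit-identical floats.
"""

from __future__ import annotations


def p_join(n_ci: int, n_cmax: int, temperature: float, join_threshold: float) -> float:
    """Probability that a lone agent joins a candidate cluster of size ``n_ci``.

    Parameters
    ----------
    n_ci
        Size of the candidate cluster (1 for a lone prospective partner).
    n_cmax
        Group size, the maximum attainable cluster size.
    temperature
        Temperature T >= 1 on the model scale.
    join_threshold
        Joining threshold J >= 1.

    Returns
    -------
    float
        Probability in [0, 1]; strictly increasing in ``n_ci``, strictly
        decreasing in ``temperature`` and ``join_threshold``.
    """
    if n_cmax < 1:
        raise ValueError(f"n_cmax must be >= 1, got {n_cmax}")
    if not 1 <= n_ci <= n_cmax:
        raise ValueError(f"n_ci must be in [1, n_cmax={n_cmax}], got {n_ci}")
    if temperature < 1:
        raise ValueError(f"temperature must be >= 1, got {temperature}")
    if join_threshold < 1:
        raise ValueError(f"join_threshold must be >= 1, got {join_threshold}")
    return (n_ci / n_cmax) * (1.0 / temperature) * (1.0 / join_threshold)


def p_leave(n_ci: int, n_cmax: int, leave_threshold: float) -> float:
    """Probability that a clustered agent leaves its cluster of size ``n_ci``.

    Zero when the whole group shares one cluster (``n_ci == n_cmax``), which
    makes the full huddle an absorbing state.
    """
    if n_cmax < 1:
        raise ValueError(f"n_cmax must be >= 1, got {n_cmax}")
    if not 1 <= n_ci <= n_cmax:
        raise ValueError(f"n_ci must be in [1, n_cmax={n_cmax}], got {n_ci}")
    if leave_threshold <= 0:
        raise ValueError(f"leave_threshold must be > 0, got {leave_threshold}")
    return ((n_cmax - n_ci) / n_cmax) * (1.0 / leave_threshold)
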