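"""Brute-force reference implementations used only by the tests.

Everything here recomputes frequencies and estimators from first principles
(pure-Python loops, literal formula transcription), independently of the
package's vectorised data path.
"""

from __future__ import annotations


def oracle_counts(rows: list[list[int]]) -> tuple[int, int, dict[int, int]]:
    """(T, S_obs, {k: Q_k}) by explicit iteration over a list-of-lists matrix."""
    T = len(rows[0]) if rows else 0
    q: dict[int, int] = {}
    s_obs = 0
    for row in rows:
        k = sum(1 for cell in row if cell == 1)
        if k > 0:
            s_obs += 1
            q[k] = q.get(k, 0) + 1
    return T, s_obs, q


def oracle_chao2(T: int, s_obs: int, q: dict[int, int]) -> float:
    q1, q2 = q.get(1, 0), q.get(2, 0)
    if q2 > 0:
        return s_obs + ((T - 1) / T) * q1 * q1 / (2 * q2)
    return s_obs + ((T - 1) / T) * q1 * (q1 - 1) / (2 * (q2 + 1))


def oracle_jackknife1(T: int, s_obs: int, q: dict[int, int]) -> float:
    return s_obs + q.get(1, 0) * (T - 1) / T


def oracle_jackknife2(T: int, s_obs: int, q: dict[int, int]) -> float:
    q1, q2 = q.get(1, 0), q.get(2, 0)
    return s_obs + q1 * (2 * T - 3) / T - q2 * (T - 2) ** 2 / (T * (T - 1))


def oracle_singletons(q: dict[int, int]) -> float:
    """Good-Turing true-unique prediction; raises when Q3 = Q4 = 0."""
    q2, q3, q4 = q.get(2, 0), q.get(3, 0), q.get(4, 0)
    if 3 * q3 + 4 * q4 == 0:
        raise ZeroDivisionError("Q3 = Q4 = 0")
    return 2 * q2 * (q2 + q3) / (3 * q3 + 4 * q4)


def oracle_chiu_chao(T: int, s_obs: int, q: dict[int, int]) -> float:
    """Singleton-corrected Chao2; plain Chao2 when Q3 = Q4 = 0."""
    if q.get(3, 0) == 0 and q.get(4, 0) == 0:
        return oracle_chao2(T, s_obs, q)
    q1_hat = oracle_singletons(q)
    q2 = q.get(2, 0)
    if q2 > 0:
        q0 = ((T - 1) / T) * q1_hat * q1_hat / (2 * q2)
    else:
        q0 = ((T - 1) / T) * q1_hat * (q1_hat - 1) / (2 * (q2 + 1))
    return s_obs - q.get(1, 0) + q1_hat + q0


def oracle_ice(rows: list[list[int]], threshold: int = 10) -> float:
    """Coverage-based estimator evaluated by hand from the matrix."""
    T, s_obs, _ = oracle_counts(rows)
    if s_obs == 0:
        return 0.0
    incid = [sum(row) for row in rows]
    infreq = [i for i, k in enumerate(incid) if 1 <= k <= threshold]
    freq = [i for i, k in enumerate(incid) if k > threshold]
    if not infreq:
        return float(s_obs)
    n_inf = sum(incid[i] for i in infreq)
    q1 = sum(1 for i in infreq if incid[i] == 1)
    coverage = 1 - q1 / n_inf
    if coverage == 0:
        return oracle_chao2(*oracle_counts(rows))
    t_inf = sum(
        1 for j in range(T) if any(rows[i][j] == 1 for i in infreq)
    )
    ssq = sum(incid[i] * (incid[i] - 1) for i in infreq)
    gamma2 = max(
        (len(infreq) / coverage) * (t_inf / (t_inf - 1)) * ssq / n_inf**2 - 1, 0.0
    )
    return len(freq) + len(infreq) / coverage + (q1 / coverage) * gamma2
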