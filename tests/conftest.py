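import pytest
from hypothesis import HealthCheck, settings

from hknot import Sequence

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# the 22-nt worked example and its fully decorated reference structure
WORKED_RESIDUES = "ACAUCCGCCUGAUUUGAGCACA"
WORKED_DECORATED_DB = "[.[[[.((((]]].].))).)."


@pytest.fixture
def worked_seq() -> Sequence:
    return Sequence("worked", WORKED_RESIDUES)


def brute_force_core_stems(seq, allow_gu=False, min_left_loop=1, min_right_loop=1):
    """Independent quadruple-nested-loop enumeration of core-stem candidates."""
    allowed = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
    if allow_gu:
        allowed |= {("G", "U"), ("U", "G")}
    res = seq.residues
    n = len(res)
    out = set()
    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            for k in range(j + 1, n + 1):
                for l in range(k + 1, n + 1):
                    if (
                        (res[i - 1], res[k - 1]) in allowed
                        and (res[j - 1], res[l - 1]) in allowed
                        and j - i - 1 >= min_left_loop
                        and l - k - 1 >= min_right_loop
                    ):
                        out.add((i, j, k, l))
    return out
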