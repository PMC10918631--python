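import sys

import pytest

from entnorm.dictionary import build_dictionary

sys.setrecursionlimit(200_000)


def oracle_levenshtein():
    """Independent memoized-recursive edit distance (suffix decomposition).

    The memo is shared across calls so exhaustive sweeps over a small
    alphabet stay cheap; the recursion itself never consults the
    production DP implementation.
    """
    memo = {}

    def rec(a: str, b: str) -> int:
        key = (a, b)
        if key in memo:
            return memo[key]
        if not a:
            r = len(b)
        elif not b:
            r = len(a)
        else:
            r = min(
                rec(a[1:], b) + 1,
                rec(a, b[1:]) + 1,
                rec(a[1:], b[1:]) + (a[0] != b[0]),
            )
        memo[key] = r
        return r

    return rec


@pytest.fixture(scope="session")
def oracle():
    return oracle_levenshtein()


@pytest.fixture()
def drug_dict():
    return build_dictionary(
        [
            ("Imatinib", "CHEMBL:941"),
            ("Gleevec", "CHEMBL:941"),
            ("Dasatinib", "CHEMBL:1421"),
            ("lung cancer", "DOID:1324"),
            ("ductal carcinoma", "DOID:3007"),
            ("invasive ductal carcinoma", "DOID:3008"),
        ]
    )


OBO_FIXTURE = """\
format-version: 1.2
ontology: doid-mini

[Term]
id: T:0001
name: disease

[Term]
id: T:0002
name: cancer
is_a: T:0001 ! disease

[Term]
id: T:0003
name: lung cancer
synonym: "cancer of lung" EXACT []
is_a: T:0002 ! cancer

[Term]
id: T:0004
name: non-small cell lung carcinoma
synonym: "NSCLC" RELATED []
synonym: "Non-small cell lung cancer" EXACT []
is_a: T:0003 ! lung cancer

[Term]
id: T:0005
name: hepatitis
is_a: T:0001 ! disease

[Term]
id: T:0006
name: obsolete lung tumour
is_obsolete: true
is_a: T:0003 ! lung cancer

[Typedef]
id: part_of
name: part of
"""


@pytest.fixture()
def obo_file(tmp_path):
    path = tmp_path / "mini.obo"
    path.write_text(OBO_FIXTURE, encoding="utf-8")
    return path
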