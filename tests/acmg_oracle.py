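"""Independent brute-force transcription of the ACMG-AMP combining table.

Each published rule is one entry in a literal list; the call is derived by
checking every rule.  Kept deliberately separate from (and structurally
unlike) ``autogvp.acmg_engine.combine`` so the two can be diff-tested over
the full bounded count space.
"""

from itertools import product


def oracle_call(vs, st, mo, su, sa, sb, pb) -> str:
    """Five-level call from bucket counts, one predicate per published rule."""
    pathogenic_rules = [
        vs >= 1 and st >= 1,              # 1 VeryStrong + >=1 Strong
        vs >= 1 and mo >= 2,              # 1 VeryStrong + >=2 Moderate
        vs >= 1 and mo >= 1 and su >= 1,  # 1 VeryStrong + 1 Moderate + 1 Supporting
        vs >= 1 and su >= 2,              # 1 VeryStrong + >=2 Supporting
        st >= 2,                          # >=2 Strong
        st >= 1 and mo >= 3,              # 1 Strong + >=3 Moderate
        st >= 1 and mo >= 2 and su >= 2,  # 1 Strong + 2 Moderate + >=2 Supporting
        st >= 1 and mo >= 1 and su >= 4,  # 1 Strong + 1 Moderate + >=4 Supporting
    ]
    likely_pathogenic_rules = [
        vs >= 1 and mo >= 1,              # 1 VeryStrong + 1 Moderate
        st >= 1 and mo >= 1,              # 1 Strong + 1-2 Moderate
        st >= 1 and su >= 2,              # 1 Strong + >=2 Supporting
        mo >= 3,                          # >=3 Moderate
        mo >= 2 and su >= 2,              # 2 Moderate + >=2 Supporting
        mo >= 1 and su >= 4,              # 1 Moderate + >=4 Supporting
    ]
    benign_rules = [
        sa >= 1,                          # BA1 stand-alone
        sb >= 2,                          # >=2 Strong benign
    ]
    likely_benign_rules = [
        sb >= 1 and pb >= 1,              # 1 Strong benign + 1 Supporting benign
        pb >= 2,                          # >=2 Supporting benign
    ]

    pathogenic_side = any(pathogenic_rules) or any(likely_pathogenic_rules)
    benign_side = any(benign_rules) or any(likely_benign_rules)
    if pathogenic_side and benign_side:
        return "VUS"  # contradictory evidence
    if any(pathogenic_rules):
        return "P"
    if any(likely_pathogenic_rules):
        return "LP"
    if any(benign_rules):
        return "B"
    if any(likely_benign_rules):
        return "LB"
    return "VUS"


#: Bounds of the exhaustively enumerated count space.
BOUNDS = {
    "very_strong": 1,
    "strong": 5,
    "moderate": 7,
    "supporting": 6,
    "standalone_benign": 1,
    "strong_benign": 4,
    "supporting_benign": 6,
}


def all_count_tuples():
    """Every count tuple within BOUNDS (inclusive)."""
    return product(*(range(b + 1) for b in BOUNDS.values()))
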