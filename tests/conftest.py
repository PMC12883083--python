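import textwrap

import pytest

from kinforge.gedcom_io import parse_gedcom
from kinforge.pedigree_graph import build_graph

NUCLEAR_GED = textwrap.dedent("""\
    0 HEAD
    1 GEDC
    2 VERS 5.5.1
    1 CHAR UTF-8
    0 @I1@ INDI
    1 NAME John /Smith/
    1 SEX M
    1 BIRT
    2 DATE 1950
    1 FAMS @F1@
    0 @I2@ INDI
    1 NAME Mary /Jones/
    1 SEX F
    1 BIRT
    2 DATE 1952
    1 FAMS @F1@
    0 @I3@ INDI
    1 NAME Alice /Smith/
    1 SEX F
    1 BIRT
    2 DATE 1975
    1 FAMC @F1@
    0 @I4@ INDI
    1 NAME Bob /Smith/
    1 SEX M
    1 BIRT
    2 DATE 1978
    1 FAMC @F1@
    0 @F1@ FAM
    1 HUSB @I1@
    1 WIFE @I2@
    1 CHIL @I3@
    1 CHIL @I4@
    0 TRLR
    """)


def _indi(i, name, sex, year, famc=(), fams=()):
    lines = [f"0 @I{i}@ INDI", f"1 NAME {name}", f"1 SEX {sex}",
             "1 BIRT", f"2 DATE {year}"]
    lines += [f"1 FAMC {f}" for f in famc]
    lines += [f"1 FAMS {f}" for f in fams]
    return lines


def _fam(i, husb=None, wife=None, children=()):
    lines = [f"0 @F{i}@ FAM"]
    if husb:
        lines.append(f"1 HUSB {husb}")
    if wife:
        lines.append(f"1 WIFE {wife}")
    lines += [f"1 CHIL {c}" for c in children]
    return lines


def make_gedcom(indis, fams):
    lines = ["0 HEAD", "1 GEDC", "2 VERS 5.5.1", "1 CHAR UTF-8"]
    for args in indis:
        lines += _indi(*args)
    for args in fams:
        lines += _fam(*args)
    lines.append("0 TRLR")
    return "\n".join(lines) + "\n"


# Three-generation, two-branch pedigree: grandparent couple @F1@ with
# children @I3@ (parent of match @I7@) and @I4@ (parent of match @I8@), plus
# a third child @I5@ whose family @F4@ is the natural attachment point for a
# hidden grandchild. Mirrors the worked two-match convergence example.
TWO_BRANCH_GED = make_gedcom(
    indis=[
        (1, "George /Root/", "M", 1900, (), ("@F1@",)),
        (2, "Anna /Root/", "F", 1902, (), ("@F1@",)),
        (3, "Carl /Root/", "M", 1930, ("@F1@",), ("@F2@",)),
        (4, "Dora /Root/", "F", 1932, ("@F1@",), ("@F3@",)),
        (5, "Edwin /Root/", "M", 1934, ("@F1@",), ("@F4@",)),
        (6, "Fay /Miller/", "F", 1931, (), ("@F2@",)),
        (9, "Hugh /Brown/", "M", 1933, (), ("@F3@",)),
        (10, "Iris /Stone/", "F", 1936, (), ("@F4@",)),
        (7, "Mark /Root/", "M", 1960, ("@F2@",), ()),
        (8, "Nina /Brown/", "F", 1962, ("@F3@",), ()),
    ],
    fams=[
        (1, "@I1@", "@I2@", ("@I3@", "@I4@", "@I5@")),
        (2, "@I3@", "@I6@", ("@I7@",)),
        (3, "@I9@", "@I4@", ("@I8@",)),
        (4, "@I5@", "@I10@", ()),
    ],
)

# Two sibling pairs intermarried -> their children are double first cousins.
DOUBLE_COUSIN_GED = make_gedcom(
    indis=[
        (1, "A /X/", "M", 1900, (), ("@F1@",)),
        (2, "B /X/", "F", 1902, (), ("@F1@",)),
        (3, "C /Y/", "M", 1901, (), ("@F2@",)),
        (4, "D /Y/", "F", 1903, (), ("@F2@",)),
        (5, "E /X/", "M", 1925, ("@F1@",), ("@F3@",)),
        (6, "F /X/", "F", 1927, ("@F1@",), ("@F4@",)),
        (7, "G /Y/", "F", 1926, ("@F2@",), ("@F3@",)),
        (8, "H /Y/", "M", 1928, ("@F2@",), ("@F4@",)),
        (9, "I /X/", "M", 1950, ("@F3@",), ()),
        (10, "J /Y/", "F", 1952, ("@F4@",), ()),
    ],
    fams=[
        (1, "@I1@", "@I2@", ("@I5@", "@I6@")),
        (2, "@I3@", "@I4@", ("@I7@", "@I8@")),
        (3, "@I5@", "@I7@", ("@I9@",)),
        (4, "@I8@", "@I6@", ("@I10@",)),
    ],
)

# One shared parent: @I3@ and @I4@ are half-siblings through @I1@.
HALF_SIB_GED = make_gedcom(
    indis=[
        (1, "Pat /Z/", "M", 1900, (), ("@F1@", "@F2@")),
        (2, "Quin /W/", "F", 1902, (), ("@F1@",)),
        (5, "Rae /V/", "F", 1905, (), ("@F2@",)),
        (3, "Sam /Z/", "M", 1930, ("@F1@",), ()),
        (4, "Tess /Z/", "F", 1932, ("@F2@",), ()),
    ],
    fams=[
        (1, "@I1@", "@I2@", ("@I3@",)),
        (2, "@I1@", "@I5@", ("@I4@",)),
    ],
)


@pytest.fixture
def nuclear_doc():
    return parse_gedcom(NUCLEAR_GED)[0]


@pytest.fixture
def nuclear_graph(nuclear_doc):
    return build_graph(nuclear_doc)


@pytest.fixture
def two_branch_graph():
    return build_graph(parse_gedcom(TWO_BRANCH_GED)[0])


@pytest.fixture
def double_cousin_graph():
    return build_graph(parse_gedcom(DOUBLE_COUSIN_GED)[0])


@pytest.fixture
def half_sib_graph():
    return build_graph(parse_gedcom(HALF_SIB_GED)[0])
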