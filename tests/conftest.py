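import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


# Published catalogue of proteins <= 50 aa in the Synechocystis 6803 chromosome
# and plasmids: (start, end, strand, printed length in aa, includes_stop).
# All rows follow the stop-inclusive convention except hliR1, whose printed span
# (1606868-1606978, 111 nt) matches the stop-free coding sequence.
TABLE2_ROWS = [
    (608828, 608748, "-", 26, True),
    (1840846, 1840926, "+", 26, True),
    (160004, 160093, "-", 29, True),       # petN
    (586617, 586525, "-", 30, True),
    (2414584, 2414679, "+", 31, True),     # psbT
    (467201, 467296, "+", 31, True),       # psaM
    (1148230, 1148325, "-", 31, True),     # norf4
    (1643502, 1643600, "-", 32, True),     # petL
    (3097275, 3097379, "+", 34, True),
    (146724, 146831, "-", 35, True),       # psbM
    (468997, 468887, "-", 36, True),
    (3118192, 3118302, "+", 36, True),     # petM
    (1606868, 1606978, "+", 37, False),    # hliR1 (stop-free span)
    (473802, 473915, "-", 37, True),
    (32865, 32978, "-", 37, True),
    (831101, 831217, "-", 38, True),       # rpl36
    (1823570, 1823686, "+", 38, True),     # petG
    (2350140, 2350256, "-", 38, True),     # psbI
    (571084, 571203, "+", 39, True),       # psbL
    (571236, 571355, "+", 39, True),       # psbJ
    (1268189, 1268308, "-", 39, True),     # psbY
    (2613481, 2613600, "-", 39, True),     # psbX
    (2816991, 2817110, "-", 39, True),
    (3140045, 3140164, "-", 39, True),     # ycf12
    (1687326, 1687448, "-", 40, True),     # psaJ
    (3458023, 3458145, "+", 40, True),     # psaI
    (3188105, 3188227, "-", 40, True),     # ndhP
    (2138496, 2138621, "+", 41, True),
    (633626, 633754, "+", 42, True),
    (273512, 273381, "-", 43, True),
    (1167333, 1167464, "+", 43, True),     # psbN
    (570940, 571074, "+", 44, True),       # psbF
    (3067172, 3067306, "-", 44, True),
    (30142, 30008, "-", 44, True),
    (553065, 553202, "-", 45, True),       # psbK
    (1826764, 1826901, "+", 45, True),     # rpl34
    (903627, 903764, "-", 45, True),
    (14477, 14340, "-", 45, True),
    (1842716, 1842856, "-", 46, True),     # ndhQ
    (1141803, 1141946, "-", 47, True),     # hliC
    (298826, 298972, "-", 48, True),       # norf1
    (572978, 573124, "-", 48, True),
    (159812, 159961, "-", 49, True),
    (2595112, 2595264, "-", 50, True),
]


@pytest.fixture(scope="session")
def table2_rows():
    return TABLE2_ROWS
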