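"""Reference worked example: 45 significant SNP positions on five rabbit
chromosomes and the 24 QTL intervals they cluster into under the
gap<=100kb single-linkage rule."""

# (chromosome, position bp)
SIGNIFICANT_SNPS = [
    ("OCU2", 7_392_553),
    ("OCU2", 8_791_893),
    ("OCU2", 10_501_993),
    ("OCU2", 10_591_957),
    ("OCU2", 11_378_860),
    ("OCU2", 13_386_997),
    ("OCU2", 13_488_329),
    ("OCU2", 13_770_022),
    ("OCU2", 13_775_984),
    ("OCU2", 13_847_789),
    ("OCU2", 13_885_731),
    ("OCU2", 14_218_502),
    ("OCU2", 14_381_825),
    ("OCU2", 14_388_318),
    ("OCU2", 15_540_704),
    ("OCU2", 19_348_590),
    ("OCU2", 19_519_932),
    ("OCU2", 21_766_582),
    ("OCU2", 21_961_157),
    ("OCU2", 21_961_341),
    ("OCU2", 21_991_030),
    ("OCU2", 22_076_402),
    ("OCU2", 22_080_992),
    ("OCU2", 22_082_402),
    ("OCU2", 22_151_345),
    ("OCU2", 22_287_659),
    ("OCU2", 22_552_417),
    ("OCU2", 22_559_081),
    ("OCU2", 22_559_709),
    ("OCU2", 22_559_791),
    ("OCU2", 22_585_579),
    ("OCU2", 22_597_775),
    ("OCU2", 22_628_803),
    ("OCU2", 22_632_153),
    ("OCU2", 22_674_072),
    ("OCU2", 24_405_104),
    ("OCU2", 31_443_212),
    ("OCU2", 31_466_952),
    ("OCU2", 58_261_249),
    ("OCU2", 65_306_234),
    ("OCU2", 65_396_063),
    ("OCU4", 19_121_968),
    ("OCU9", 35_523_218),
    ("OCU11", 64_951_640),
    ("OCU19", 52_159_278),
]

# (chromosome, start bp, end bp) of the expected QTL regions
EXPECTED_QTL_REGIONS = [
    ("OCU2", 7_292_553, 7_492_553),
    ("OCU2", 8_691_893, 8_891_893),
    ("OCU2", 10_401_993, 10_691_957),
    ("OCU2", 11_278_860, 11_478_860),
    ("OCU2", 13_286_997, 13_486_997),
    ("OCU2", 13_388_329, 13_588_329),
    ("OCU2", 13_670_022, 13_985_731),
    ("OCU2", 14_118_502, 14_318_502),
    ("OCU2", 14_281_825, 14_488_318),
    ("OCU2", 15_440_704, 15_640_704),
    ("OCU2", 19_248_590, 19_448_590),
    ("OCU2", 19_419_932, 19_619_932),
    ("OCU2", 21_666_582, 21_866_582),
    ("OCU2", 21_861_157, 22_251_345),
    ("OCU2", 22_187_659, 22_387_659),
    ("OCU2", 22_452_417, 22_774_072),
    ("OCU2", 24_305_104, 24_505_104),
    ("OCU2", 31_343_212, 31_566_952),
    ("OCU2", 58_161_249, 58_361_249),
    ("OCU2", 65_206_234, 65_496_063),
    ("OCU4", 19_021_968, 19_221_968),
    ("OCU9", 35_423_218, 35_623_218),
    ("OCU11", 64_851_640, 65_051_640),
    ("OCU19", 52_059_278, 52_259_278),
]
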