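clade,age
angiosperms,179
mesangiospermae,158
magnoliids,147
core_eudicots,116
rosids,110
fabids,104
rosales_fagales,94
sapindales,78
asterids,107
core_asterids,104
ericales,100
core_ericales,93
theoids,88
styracoids,80
ericoids,85
euasterids,98
campanulids,92
Magnoliaceae,95
Lauraceae,90
Ericaceae,70
Araliaceae,60
Oleaceae,55
Rosaceae,76
Rutaceae,65
Sapindaceae,58
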