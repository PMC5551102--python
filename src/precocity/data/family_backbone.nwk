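(Schisandraceae,((Magnoliaceae,Lauraceae)magnoliids,(((Euphorbiaceae,(Rosaceae,Fagaceae)rosales_fagales)fabids,(Sapindaceae,Rutaceae)sapindales)rosids,(Cornaceae,((Pentaphylacaceae,((Theaceae,(Styracaceae,Symplocaceae)styracoids)theoids,(Clethraceae,Ericaceae)ericoids)core_ericales)ericales,(Oleaceae,(Aquifoliaceae,Araliaceae)campanulids)euasterids)core_asterids)asterids)core_eudicots)mesangiospermae)angiosperms;
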