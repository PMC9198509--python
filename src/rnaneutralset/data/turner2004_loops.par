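## RNAfold parameter file v2.0

# Turner 2004 nearest-neighbour loop parameters (free energies at 37 C,
# dcal/mol), trimmed to the loop-initiation sections used by the
# sequence-independent loop free energy G_loop: hairpin, bulge and internal
# loop initiation by size (0..30), the NINIO internal-loop asymmetry term and
# the multiloop coefficients.  Sequence-dependent tables (stacking, mismatch,
# dangle, special loops) are deliberately absent.

# hairpin
   INF   INF   INF   540   560   570   540   600   550   640
   650   660   670   680   690   690   700   710   710   720
   720   730   730   740   740   750   750   750   760   760
   770

# bulge
   INF   380   280   320   360   400   440   460   470   480
   490   500   510   520   530   540   540   550   550   560
   570   570   580   580   580   590   590   600   600   600
   610

# internal
   INF   INF   100   100   110   200   200   210   230   240
   250   260   270   280   290   290   300   310   310   320
   330   330   340   340   350   350   350   360   360   370
   370

# NINIO
     60     320     300

# ML_params
      0       0     930    3000     -90    -220

#END
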