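# Reference classes for plant-available field capacity (nFK, mm) in the rooted
# zone, by soil texture class and soil quality number (Bodenzahl).  An interval
# covers soil numbers lo_exclusive < n <= hi_inclusive; empty hi_inclusive
# means open-ended upward.  version: 1
soil_type,lo_exclusive,hi_inclusive,nfk_mm
S,0,21,50
S,21,37,90
S,37,,140
Sl,0,17,50
Sl,17,31,90
Sl,31,47,140
Sl,47,,200
lS,0,18,50
lS,18,32,90
lS,32,49,140
lS,49,71,200
lS,71,,250
SL,0,17,50
SL,17,31,90
SL,31,48,140
SL,48,69,200
SL,69,86,250
SL,86,,270
sL,0,18,50
sL,18,33,90
sL,33,51,140
sL,51,73,200
sL,73,92,250
sL,92,,270
L,0,17,50
L,17,31,90
L,31,48,140
L,48,69,200
L,69,86,250
L,86,95,270
L,95,,300
LC,0,21,50
LC,21,38,90
LC,38,59,140
LC,59,84,200
LC,84,,250
C,0,21,50
C,21,38,90
C,38,60,140
C,60,,200
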