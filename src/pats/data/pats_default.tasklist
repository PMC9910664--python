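# pats task list
# provenance: built-in PATS defaults
threshold lo=55 hi=255
shrinkwrap diameter=4 stretch_over_holes=true
reload
threshold lo=0 hi=55
bitwise dst=roi a=selection op=AND b=roi
despeckle mode=sweep_keep_largest space=3D target=roi
despeckle mode=sweep_keep_largest space=3D target=roi optional=true enabled=false
save_bitmaps name=aerated_lung
analyze name=aerated_lung values=basic
model name=aerated_lung format=stl
morphology op=closing shape=round radius=40 space=2D target=roi
bitwise dst=roi a=selection op=AND b=roi optional=true enabled=false
save_bitmaps name=roi_for_modification optional=true enabled=false
reload
threshold lo=55 hi=255
morphology op=erosion shape=round radius=1 space=2D target=selection
bitwise dst=roi a=roi op=AND b=selection
save_bitmaps name=lung_tissue
analyze name=lung_tissue values=basic,additional
model name=lung_tissue format=stl
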