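class,resistance
crop_pasture,10
grassland,10
large_rivers,10
rock_barren,10
sand_gravel,10
settlement,100
transportation,100
wooded_area,10
wetlands,1
water,1
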