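item,land_type,account,average_yield,energy_footprint_density,convert_coefficient,unit
grain,croplands,biological,5453.472,,,kg
oil,croplands,biological,2189.756,,,kg
vegetables_and_edible_fungi,croplands,biological,28912.615,,,kg
sugarcane,croplands,biological,46910.696,,,kg
tobacco,croplands,biological,2112.329,,,kg
tea,forests,biological,804.813,,,kg
garden_fruit,forests,biological,2459.02,,,kg
cocoons,forests,biological,600,,,kg
meat,grazing_lands,biological,5592.36,,,kg
milk,grazing_lands,biological,494.10,,,kg
eggs,grazing_lands,biological,1151.27,,,kg
aquatic_products,fishing_grounds,biological,1475.079,,,kg
raw_coal,carbon_capture_land,energy,,55,20.934,ton
natural_gas,carbon_capture_land,energy,,93,18.003,ton
gasoline,carbon_capture_land,energy,,93,43.124,ton
diesel,carbon_capture_land,energy,,93,42.705,ton
coke,carbon_capture_land,energy,,55,28.47,ton
electricity,built_up,energy,,1000,11.84,1e4_kWh
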