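# Seawater and swim-bladder gas parameters for the five study environments:
# two surface environments (warm 20.0 C, cold 1.5 C) and three cold deep-water
# environments (1000 m, 2000 m, 3500 m), all at salinity 35.0 g/kg.
# Values are stored in the units given below and converted to SI on load.
units:
  depth: m
  temperature: degC
  salinity: g/kg
  ambient_pressure: MPa
  water_density: kg/m^3
  water_dynamic_viscosity: mPa s
  water_surface_tension: mN/m
  water_sound_speed: m/s
  gamma: dimensionless
  thermal_diffusivity: 1e-9 m^2/s
environments:
  - name: warm_surface
    depth: 0.0
    temperature: 20.0
    salinity: 35.0
    ambient_pressure: 0.101325
    water_density: 1028.0
    water_dynamic_viscosity: 1.077
    water_surface_tension: 73.52
    water_sound_speed: 1522.0
    gases:
      N2: {gamma: 1.401, thermal_diffusivity: 21000.0}
      O2: {gamma: 1.397, thermal_diffusivity: 21210.0}
  - name: cold_surface
    depth: 0.0
    temperature: 1.5
    salinity: 35.0
    ambient_pressure: 0.101325
    water_density: 1027.0
    water_dynamic_viscosity: 1.812
    water_surface_tension: 76.01
    water_sound_speed: 1456.0
    gases:
      N2: {gamma: 1.402, thermal_diffusivity: 18620.0}
      O2: {gamma: 1.400, thermal_diffusivity: 18780.0}
  - name: depth_1000m
    depth: 1000.0
    temperature: 1.5
    salinity: 35.0
    ambient_pressure: 10.19
    water_density: 1032.0
    water_dynamic_viscosity: 1.812
    water_surface_tension: 76.01
    water_sound_speed: 1473.0
    gases:
      N2: {gamma: 1.612, thermal_diffusivity: 191.4}
      O2: {gamma: 1.668, thermal_diffusivity: 172.0}
  - name: depth_2000m
    depth: 2000.0
    temperature: 1.5
    salinity: 35.0
    ambient_pressure: 20.33
    water_density: 1036.0
    water_dynamic_viscosity: 1.812
    water_surface_tension: 76.01
    water_sound_speed: 1490.0
    gases:
      N2: {gamma: 1.738, thermal_diffusivity: 114.3}
      O2: {gamma: 1.897, thermal_diffusivity: 92.64}
  - name: depth_3500m
    depth: 3500.0
    temperature: 1.5
    salinity: 35.0
    ambient_pressure: 35.62
    water_density: 1043.0
    water_dynamic_viscosity: 1.812
    water_surface_tension: 76.01
    water_sound_speed: 1516.0
    gases:
      N2: {gamma: 1.760, thermal_diffusivity: 95.38}
      O2: {gamma: 1.950, thermal_diffusivity: 74.87}
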