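peak_name,B0,B1,se_B0,se_B1,R2,Syx
peak_7.28,1.13e-5,1.73e-6,4.18e-6,2.52e-8,0.9994,2.39e-6
peak_8.73,-2.6e-5,4.88e-6,1.99e-5,1.2e-7,0.998,1.14e-5
peak_9.02,4.36e-5,1.73e-6,1.55e-5,9.33e-8,0.991,8.85e-6
peak_9.30,0.000105,8.27e-6,2.82e-5,1.7e-7,0.998,1.61e-5
peak_9.80,3.06e-5,1.32e-6,7.07e-6,4.27e-8,0.997,4.05e-6
peak_10.43,0.000177,2.96e-5,1.29e-4,7.8e-7,0.998,7.4e-5
peak_11.99,3.45e-5,3.62e-5,1.45e-4,8.79e-7,0.998,8.34e-5
peak_12.53,2.0e-6,3.0e-6,6.83e-6,4.13e-8,0.9994,3.92e-6
peak_12.76,1.29e-4,7.74e-6,1.69e-5,1.02e-7,0.9995,9.71e-6
peak_13.18,2.35e-5,1.61e-5,3.82e-5,2.31e-7,0.9994,2.19e-5
peak_14.35,-3e-5,1.54e-5,4.29e-5,2.59e-7,0.9996,2.46e-5
peak_17.18,1.19e-5,1.59e-6,5.98e-6,3.61e-8,0.998,3.43e-6
peak_18.95,1.11e-5,1.18e-6,5.73e-6,3.46e-8,0.997,3.28e-6
peak_19.33,1.02e-4,1.07e-5,2.4e-5,1.45e-7,0.9994,1.38e-5
peak_20.27,6.23e-5,4.29e-6,1.12e-5,6.79e-8,0.9993,6.44e-6
peak_20.87,3.0e-6,1.29e-6,1.23e-5,7.41e-8,0.990,7.03e-6
peak_21.33,-3.8e-5,8.46e-6,2.03e-5,1.23e-7,0.9994,1.16e-5
peak_21.75,-3.2e-5,4.77e-6,2.36e-5,1.43e-7,0.997,1.35e-5
peak_22.12,1.63e-5,3.82e-6,1.44e-5,8.68e-8,0.998,8.24e-6
peak_22.70,-9.4e-5,1.13e-5,2.47e-5,1.49e-7,0.9995,1.41e-5
peak_23.13,-4.7e-7,1.24e-5,3.11e-5,1.88e-7,0.9993,1.78e-5
peak_23.65,-6.4e-5,1.08e-5,3.77e-5,2.28e-7,0.998,2.16e-5
peak_24.20,4.26e-4,3.72e-6,3.07e-5,1.86e-7,0.992,1.76e-5
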