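facility_kind,label,category,annual_cost_zmk,n_patients
district_hospital,building,capital,62027654.38,6000
district_hospital,furniture,capital,4843934.37,6000
district_hospital,staff_salary,recurrent,708756919.89,6000
district_hospital,cd4_fbc_testing,drug_lab,468000000.00,6000
district_hospital,chemistry_testing,drug_lab,150000000.00,6000
district_hospital,arv,drug_lab,6000000000.00,6000
rural_health_centre,building,capital,3101382.72,300
rural_health_centre,furniture,capital,150545.30,300
rural_health_centre,staff_salary,recurrent,57772379.80,300
rural_health_centre,vehicle,capital,5332881.49,300
rural_health_centre,cd4_fbc_testing,drug_lab,23400000.00,300
rural_health_centre,chemistry_testing,drug_lab,7500000.00,300
rural_health_centre,arv,drug_lab,300000000.00,300
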