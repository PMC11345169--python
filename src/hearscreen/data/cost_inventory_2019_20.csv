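modality,category,description,amount,lifespan_years,monthly_salary,apportioning_statistic
P-AABR,human_resource,staff nurse,,,15000,1
P-AABR,human_resource,data entry operator/technician,,,18000,1
P-AABR,human_resource,post service training,25000,,,
P-AABR,medical_consumables,electrodes,104520,,,
P-AABR,medical_equipment,portable automated ABR device,448416,6,,
P-AABR,overheads,electricity and water,2400,,,
OAE,human_resource,staff nurse,,,15000,1
OAE,human_resource,data entry operator/technician,,,18000,1
OAE,human_resource,post service training,25000,,,
OAE,medical_consumables,probe tips and consumables,140400,,,
OAE,medical_equipment,OAE device,353298,6,,
OAE,overheads,electricity and water,2400,,,
BERA,human_resource,audiologist,,,50000,1
BERA,human_resource,staff nurse,,,15000,1
BERA,human_resource,data entry operator/technician,,,18000,1
BERA,human_resource,pediatrician/anesthesiologist,,,90000,0.25
BERA,human_resource,post service training,25000,,,
BERA,medical_consumables,electrodes and sedatives,174720,,,
BERA,non_medical_consumables,stationery and cartridge,4000,,,
BERA,medical_equipment,BERA system,1122642,6,,
BERA,non_medical_equipment,soundproof room and building/space,139354,,,
BERA,overheads,electricity and water,30000,,,
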